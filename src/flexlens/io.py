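"""Readers and writers for the plain-text formats the pipeline touches.

Dialects:

* classic DSSP residue blocks (header line ``  #  RESIDUE AA``, structure
  code at column 17; blank code means coil);
* FASTA (via Bio.SeqIO);
* a label-matrix TSV serialising per-frame DSSP output — header
  ``frame<TAB>id1<TAB>id2...``, one row per frame with the time in ps
  followed by one Q8 code per residue (``-`` is accepted as coil);
* PSIPRED ``.ss2``-style prediction tables — ``idx aa label p_C p_H p_E``
  for Q3, and an eight-probability variant (columns ordered H,G,I,E,B,T,S,C)
  for Q8;
* IUPred-style disorder tables — ``pos<TAB>aa<TAB>score``, ``#`` comments;
* BED-style region files (0-based half-open on disk, 1-based inclusive in
  memory);
* a long-format coordinate table ``frame residue x y z`` in A.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError
from .types import (
    CoordinateTrajectory,
    DisorderProfile,
    LabelTrajectory,
    PredictionProfile,
    Q8_SET,
    ReferenceStructure,
    Region,
    RegionSet,
    class_codes,
)

_DSSP_HEADER = "#  RESIDUE AA"


# ---------------------------------------------------------------------------
# DSSP
# ---------------------------------------------------------------------------

def read_dssp(path, chain: str | None = None, protein_id: str | None = None) -> ReferenceStructure:
    """Parse a classic DSSP file into a :class:`ReferenceStructure`.

    Blank structure codes become coil ('C'); chain-break rows ('!') are
    skipped; lowercase amino-acid letters (DSSP's disulfide convention) are
    read as cysteine.  A ``chain`` selector is required when the file holds
    more than one chain.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = None
    for k, line in enumerate(lines):
        if _DSSP_HEADER in line:
            start = k + 1
            break
    if start is None:
        raise FormatError(f"{path}: no DSSP residue block (header '  #  RESIDUE AA') found")

    seq: list[str] = []
    labels: list[str] = []
    rids: list[int] = []
    chains_seen: set[str] = set()
    for k in range(start, len(lines)):
        line = lines[k]
        if not line.strip():
            continue
        if len(line) < 14:
            raise FormatError(f"{path}: truncated residue row at line {k + 1}")
        aa = line[13]
        if aa == "!":  # chain break / discontinuity rows carry no residue
            continue
        chain_id = line[11]
        if chain is not None and chain_id != chain:
            continue
        chains_seen.add(chain_id)
        code = line[16] if len(line) > 16 else " "
        if code == " ":
            code = "C"
        if code not in Q8_SET:
            raise FormatError(
                f"{path}: unknown structure code {code!r} at line {k + 1}"
            )
        try:
            rid = int(line[5:10])
        except ValueError as exc:
            raise FormatError(f"{path}: unparsable residue number at line {k + 1}") from exc
        if aa.islower():  # disulfide-bonded cysteines are lettered a, b, ...
            aa = "C"
        seq.append(aa)
        labels.append(code)
        rids.append(rid)

    if chain is None and len(chains_seen) > 1:
        raise FormatError(
            f"{path}: multiple chains present ({sorted(chains_seen)}); pass chain="
        )
    if not rids:
        raise FormatError(f"{path}: DSSP residue block contains no residues")
    return ReferenceStructure(
        protein_id=protein_id or path.stem,
        sequence="".join(seq),
        labels_q8="".join(labels),
        residue_ids=np.array(rids),
    )


def write_dssp(ref: ReferenceStructure, path, chain: str = "A") -> None:
    """Write a minimal classic-format DSSP residue block (fixture/round-trip).

    Coil is written as the conventional blank structure code.
    """
    lines = [
        "==== Secondary Structure Definition, flexlens minimal writer ====",
        f"  {len(ref)} residues",
        "  #  RESIDUE AA STRUCTURE",
    ]
    for k, (aa, code, rid) in enumerate(zip(ref.sequence, ref.labels_q8, ref.residue_ids)):
        out_code = " " if code == "C" else code
        lines.append(f"{k + 1:>5}{rid:>5} {chain} {aa}  {out_code}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Label matrix
# ---------------------------------------------------------------------------

def read_label_matrix(path) -> LabelTrajectory:
    """Read a frames x residues Q8 label matrix TSV."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty label matrix")
    header = lines[0].split("\t")
    if header[0] != "frame" or len(header) < 2:
        raise FormatError(f"{path}: header must be 'frame<TAB>residue ids...'")
    try:
        residue_ids = [int(t) for t in header[1:]]
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer residue id in header") from exc

    times: list[float] = []
    rows: list[list[str]] = []
    for rnum, line in enumerate(lines[1:], start=2):
        toks = line.split("\t")
        if len(toks) != len(residue_ids) + 1:
            raise FormatError(
                f"{path}: row {rnum} has {len(toks) - 1} labels, "
                f"expected {len(residue_ids)}"
            )
        try:
            t = float(toks[0])
        except ValueError as exc:
            raise FormatError(f"{path}: unparsable frame time at row {rnum}") from exc
        codes = ["C" if c == "-" else c for c in toks[1:]]
        for c in codes:
            if c not in Q8_SET:
                raise FormatError(f"{path}: unknown label {c!r} at row {rnum}")
        if times and t <= times[-1]:
            raise FormatError(f"{path}: non-monotone frame time at row {rnum}")
        times.append(t)
        rows.append(codes)
    return LabelTrajectory(
        residue_ids=np.array(residue_ids),
        frame_times=np.array(times),
        labels=np.array(rows, dtype="<U1"),
    )


def write_label_matrix(traj: LabelTrajectory, path) -> None:
    lines = ["frame\t" + "\t".join(str(i) for i in traj.residue_ids)]
    for t, row in zip(traj.frame_times, traj.labels):
        lines.append(f"{t:g}\t" + "\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Prediction tables
# ---------------------------------------------------------------------------

def read_prediction_table(path, scheme: str, predictor_name: str | None = None) -> PredictionProfile:
    """Read a ``.ss2``-style table (Q3) or its eight-column variant (Q8).

    Probability rows summing to within [0.99, 1.01] are renormalised; the
    file's label is kept (with a warning) when it disagrees with the argmax.
    """
    path = Path(path)
    codes = class_codes(scheme)
    n = len(codes)
    labels: list[str] = []
    probs: list[list[float]] = []
    for lnum, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        toks = stripped.split()
        if len(toks) != 3 + n:
            raise FormatError(
                f"{path}: line {lnum} has {len(toks)} fields, expected {3 + n}"
            )
        label = toks[2]
        if label not in codes:
            raise FormatError(f"{path}: line {lnum}: label {label!r} not in {codes}")
        try:
            p = [float(t) for t in toks[3:]]
        except ValueError as exc:
            raise FormatError(f"{path}: line {lnum}: unparsable probability") from exc
        if min(p) < 0 or max(p) > 1:
            raise FormatError(f"{path}: line {lnum}: probability outside [0, 1]")
        s = sum(p)
        if not 0.99 <= s <= 1.01:
            raise FormatError(
                f"{path}: line {lnum}: probabilities sum to {s:.4f}, "
                "outside [0.99, 1.01]"
            )
        p = [x / s for x in p]
        argmax_label = codes[int(np.argmax(p))]  # ties -> first in class order
        if argmax_label != label:
            warnings.warn(
                f"{path}: line {lnum}: file label {label!r} differs from "
                f"probability argmax {argmax_label!r}; keeping file label",
                stacklevel=2,
            )
        labels.append(label)
        probs.append(p)
    if not labels:
        raise FormatError(f"{path}: no prediction rows found")
    return PredictionProfile(
        predictor_name=predictor_name or path.stem,
        scheme=scheme,
        predicted_labels=np.array(labels, dtype="<U1"),
        probs=np.array(probs),
    )


def write_prediction_table(pred: PredictionProfile, path, sequence: str | None = None) -> None:
    codes = pred.class_order
    lines = [f"# flexlens prediction table scheme={pred.scheme} "
             f"classes={','.join(codes)} predictor={pred.predictor_name}"]
    for i, (label, row) in enumerate(zip(pred.predicted_labels, pred.probs)):
        aa = sequence[i] if sequence else "X"
        lines.append(f"{i + 1} {aa} {label} " + " ".join(f"{p:.6f}" for p in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Disorder tables
# ---------------------------------------------------------------------------

def read_disorder_table(path, predictor_name: str | None = None) -> DisorderProfile:
    """Read an IUPred-style ``pos aa score`` table; scores must be in [0, 1]."""
    path = Path(path)
    scores: list[float] = []
    for lnum, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        toks = stripped.split()
        if len(toks) < 3:
            raise FormatError(f"{path}: line {lnum} has fewer than 3 fields")
        try:
            s = float(toks[2])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lnum}: unparsable score") from exc
        if not 0.0 <= s <= 1.0:
            raise FormatError(
                f"{path}: score {s} out of [0, 1] at position {toks[0]}"
            )
        scores.append(s)
    if not scores:
        raise FormatError(f"{path}: no score rows found")
    return DisorderProfile(predictor_name=predictor_name or path.stem,
                           scores=np.array(scores))


def write_disorder_table(profile: DisorderProfile, path, sequence: str | None = None) -> None:
    lines = [f"# flexlens disorder table predictor={profile.predictor_name}",
             "# pos\taa\tscore"]
    for i, s in enumerate(profile.scores):
        aa = sequence[i] if sequence else "X"
        lines.append(f"{i + 1}\t{aa}\t{s:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercased sequence)`` tuples, in order."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path, width: int = 60) -> None:
    lines = []
    for rid, seq in records:
        lines.append(f">{rid}")
        for k in range(0, len(seq), width):
            lines.append(seq[k : k + width])
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Regions (BED-style)
# ---------------------------------------------------------------------------

_REGION_HEADER = "#protein_id\tstart\tend\tkind\tscore"


def write_regions(regions: RegionSet, path) -> None:
    """Write a BED-style region table (0-based half-open on disk)."""
    lines = [_REGION_HEADER]
    for r in regions:
        score = "." if np.isnan(r.score) else f"{r.score:.6g}"
        lines.append(f"{r.protein_id}\t{r.start - 1}\t{r.end}\t{r.kind}\t{score}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_regions(path) -> RegionSet:
    path = Path(path)
    regions = []
    for lnum, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        toks = stripped.split("\t")
        if len(toks) != 5:
            raise FormatError(f"{path}: line {lnum} has {len(toks)} fields, expected 5")
        pid, start0, end, kind, score = toks
        try:
            start = int(start0) + 1
            end_i = int(end)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lnum}: unparsable coordinates") from exc
        s = float("nan") if score == "." else float(score)
        regions.append(Region(pid, start, end_i, kind, s))
    return RegionSet(regions)


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def read_coordinates(path) -> CoordinateTrajectory:
    """Read a long-format ``frame residue x y z`` TSV into a trajectory."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: unreadable coordinate table: {exc}") from exc
    required = ["frame", "residue", "x", "y", "z"]
    if list(df.columns[:5]) != required:
        raise FormatError(f"{path}: columns must be {required}")
    frames = np.sort(df["frame"].unique())
    residues = np.sort(df["residue"].unique())
    if len(df) != frames.size * residues.size:
        raise FormatError(f"{path}: incomplete frame x residue grid")
    df = df.sort_values(["frame", "residue"])
    coords = df[["x", "y", "z"]].to_numpy().reshape(frames.size, residues.size, 3)
    return CoordinateTrajectory(residue_ids=residues.astype(int), coords=coords)


def write_coordinates(traj: CoordinateTrajectory, path) -> None:
    n_frames, n_res, _ = traj.coords.shape
    frame_col = np.repeat(np.arange(n_frames), n_res)
    res_col = np.tile(traj.residue_ids, n_frames)
    flat = traj.coords.reshape(-1, 3)
    df = pd.DataFrame(
        {"frame": frame_col, "residue": res_col,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
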