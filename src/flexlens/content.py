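"""Ordered-structure content scoring, Q8->Q3 mapping, and protein binning.

A protein's ordered content is quantified from runs of consecutive helix or
strand residues (after collapsing the eight DSSP states to three): each run
of length L contributes base**L, so longer uninterrupted stretches dominate,
and the total is normalised by chain length.  Populations are then split
into bins of increasing ordered content (quantile edges by default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .longevity import encode_runs
from .types import Q8_SET, Q8_TO_Q3, ReferenceStructure

_Q8_TO_Q3_TABLE = str.maketrans(Q8_TO_Q3)


def q8_to_q3(labels):
    """Map Q8 codes to Q3: H,G,I -> H; E,B -> E; T,S,C -> C.

    Accepts a string (returns a string) or a sequence/array of single-letter
    codes (returns an array).
    """
    if isinstance(labels, str):
        bad = set(labels) - Q8_SET
        if bad:
            raise InputError(f"unknown Q8 codes: {sorted(bad)}")
        return labels.translate(_Q8_TO_Q3_TABLE)
    arr = np.asarray(labels, dtype="<U1")
    bad = set(arr.ravel().tolist()) - Q8_SET
    if bad:
        raise InputError(f"unknown Q8 codes: {sorted(bad)}")
    out = arr.copy()
    for src, dst in Q8_TO_Q3.items():
        if src != dst:
            out[arr == src] = dst
    return out


@dataclass
class OrderScore:
    """Helix/strand content of one protein from run-length-exponential scoring."""

    protein_id: str
    runs: list[tuple[str, int]]  # (kind 'H'|'E', length), in sequence order
    raw_score: float
    normalized_score: float  # raw_score / length
    coil_fraction: float
    length: int


@dataclass
class BinAssignment:
    """Protein -> content-bin mapping; bin 1 is the least ordered."""

    assignments: dict[str, int]
    bin_edges: np.ndarray  # n_bins - 1 thresholds on normalized_score
    n_bins: int
    mode: str  # 'quantile' | 'fixed'


def order_score(labels_q8: str, base: float = 2.0, protein_id: str = "") -> OrderScore:
    """Score ordered content: sum of base**L over helix/strand runs, / length."""
    if base <= 1:
        raise ParameterError(f"base must be > 1, got {base}")
    if not labels_q8:
        raise InputError("cannot score an empty label string")
    q3 = q8_to_q3(labels_q8)
    runs = [(k, ln) for k, ln in encode_runs(q3) if k in ("H", "E")]
    raw = float(sum(base**ln for _, ln in runs))
    length = len(labels_q8)
    return OrderScore(
        protein_id=protein_id,
        runs=runs,
        raw_score=raw,
        normalized_score=raw / length,
        coil_fraction=q3.count("C") / length,
        length=length,
    )


def length_filter(
    refs: list[ReferenceStructure], center: int = 200, tol: int = 20
) -> list[ReferenceStructure]:
    """Keep proteins whose chain length lies within ``center +/- tol``."""
    if center < 0 or tol < 0:
        raise ParameterError("center and tol must be non-negative")
    return [r for r in refs if center - tol <= len(r) <= center + tol]


def assign_bins(
    scores: list[OrderScore],
    n_bins: int = 5,
    mode: str = "quantile",
    edges=None,
) -> BinAssignment:
    """Assign each protein to one of ``n_bins`` content bins.

    Quantile mode places edges at the k/n_bins quantiles of the normalised
    scores; fixed mode uses the caller's increasing edges.  A value equal to
    an edge falls in the lower bin.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    values = np.array([s.normalized_score for s in scores])
    if mode == "quantile":
        if values.size < n_bins:
            raise ParameterError(
                f"{values.size} proteins cannot fill {n_bins} quantile bins"
            )
        qs = np.arange(1, n_bins) / n_bins
        bin_edges = np.quantile(values, qs)
        if np.all(values == values[0]):
            warnings.warn(
                "all normalized scores identical; every protein assigned to bin 1",
                stacklevel=2,
            )
    elif mode == "fixed":
        if edges is None or len(edges) != n_bins - 1:
            raise ParameterError(f"fixed mode requires {n_bins - 1} edges")
        bin_edges = np.asarray(edges, dtype=float)
        if np.any(np.diff(bin_edges) <= 0):
            raise ParameterError("fixed edges must be strictly increasing")
    else:
        raise ParameterError(f"unknown binning mode {mode!r}")

    assignments = {
        s.protein_id: int(1 + np.sum(v > bin_edges))
        for s, v in zip(scores, values)
    }
    return BinAssignment(
        assignments=assignments, bin_edges=bin_edges, n_bins=n_bins, mode=mode
    )
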