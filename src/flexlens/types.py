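"""Shared domain containers.

Coordinate convention: residue positions are 1-based inclusive everywhere in
memory; on-disk BED output is 0-based half-open (see :mod:`flexlens.io`).

Label alphabets: the eight DSSP states are H (alpha helix), G (3_10 helix),
I (pi helix), E (extended strand), B (beta bridge), T (turn), S (bend) and
C (coil / no assignment).  The three-state scheme groups H,G,I -> helix,
E,B -> strand and T,S,C -> coil.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

#: Fixed Q8 class order (also the probability-column order of the 8-state
#: prediction table dialect).
Q8_CODES: tuple[str, ...] = ("H", "G", "I", "E", "B", "T", "S", "C")
#: Fixed Q3 class order, matching the PSIPRED ``.ss2`` column order C,H,E.
Q3_CODES: tuple[str, ...] = ("C", "H", "E")

Q8_SET = frozenset(Q8_CODES)
Q3_SET = frozenset(Q3_CODES)

#: Q8 -> Q3 state grouping.
Q8_TO_Q3: dict[str, str] = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C",
}


def class_codes(scheme: str) -> tuple[str, ...]:
    """Return the fixed class order for ``scheme`` ('Q3' or 'Q8')."""
    s = scheme.upper()
    if s == "Q3":
        return Q3_CODES
    if s == "Q8":
        return Q8_CODES
    raise InputError(f"unknown labelling scheme {scheme!r}; expected 'Q3' or 'Q8'")


def _check_labels(labels, alphabet, what: str) -> None:
    bad = set(np.unique(np.asarray(labels))) - set(alphabet)
    if bad:
        raise InputError(f"{what} contains codes outside the alphabet: {sorted(bad)}")


@dataclass
class ReferenceStructure:
    """Static reference: sequence plus per-residue Q8 labels.

    ``residue_ids`` carry the author numbering of the source structure;
    gaps are allowed (missing residues are excluded, never imputed).
    """

    protein_id: str
    sequence: str
    labels_q8: str
    residue_ids: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if not (len(self.sequence) == len(self.labels_q8) == self.residue_ids.size):
            raise InputError(
                f"{self.protein_id}: sequence ({len(self.sequence)}), labels "
                f"({len(self.labels_q8)}) and residue_ids ({self.residue_ids.size}) "
                "must have equal length"
            )
        if self.residue_ids.size and np.any(np.diff(self.residue_ids) <= 0):
            raise InputError(f"{self.protein_id}: residue_ids must be strictly increasing")
        _check_labels(list(self.labels_q8), Q8_SET, f"{self.protein_id}: labels_q8")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabelTrajectory:
    """Per-frame Q8 assignments: a frames x residues character matrix."""

    residue_ids: np.ndarray
    frame_times: np.ndarray  # ps, strictly increasing
    labels: np.ndarray  # (n_frames, n_residues) of single characters

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.ndim != 2:
            raise InputError("labels must be a 2-D frames x residues matrix")
        if self.labels.shape != (self.frame_times.size, self.residue_ids.size):
            raise InputError(
                f"labels shape {self.labels.shape} does not match "
                f"{self.frame_times.size} frames x {self.residue_ids.size} residues"
            )
        if np.any(self.frame_times < 0) or np.any(np.diff(self.frame_times) <= 0):
            raise InputError("frame_times must be non-negative and strictly increasing")
        _check_labels(self.labels, Q8_SET, "trajectory labels")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]


@dataclass
class PredictionProfile:
    """Secondary-structure predictor output: labels plus class probabilities.

    ``probs`` columns follow the fixed class order of the scheme
    (:data:`Q3_CODES` or :data:`Q8_CODES`).  Each row sums to 1 within 1e-6.
    The emitted label normally sits at the probability argmax; readers keep a
    file's label on disagreement and warn instead of failing.
    """

    predictor_name: str
    scheme: str  # 'Q3' | 'Q8'
    predicted_labels: np.ndarray
    probs: np.ndarray  # (n_residues, n_classes)

    def __post_init__(self) -> None:
        self.scheme = self.scheme.upper()
        codes = class_codes(self.scheme)
        self.predicted_labels = np.asarray(self.predicted_labels, dtype="<U1")
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.predicted_labels.size, len(codes)):
            raise InputError(
                f"probs shape {self.probs.shape} does not match "
                f"{self.predicted_labels.size} residues x {len(codes)} classes"
            )
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise InputError("class probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        if self.probs.size and np.max(np.abs(sums - 1.0)) > 1e-6:
            raise InputError("each probability vector must sum to 1 within 1e-6")
        _check_labels(self.predicted_labels, set(codes), "predicted labels")

    def __len__(self) -> int:
        return self.predicted_labels.size

    @property
    def class_order(self) -> tuple[str, ...]:
        return class_codes(self.scheme)


@dataclass
class DisorderProfile:
    """Per-residue disorder propensity in [0, 1] from one predictor."""

    predictor_name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise InputError(f"{self.predictor_name}: disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return self.scores.size


@dataclass
class Region:
    """A 1-based inclusive residue interval with a kind tag and a score."""

    protein_id: str
    start: int
    end: int
    kind: str
    score: float = float("nan")

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 1 or self.start > self.end:
            raise InputError(f"invalid region [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "Region") -> int:
        """Number of residues shared with ``other``."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class RegionSet:
    """Ordered regions, non-overlapping within each kind."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.start, r.end))
        by_kind: dict[str, Region] = {}
        for r in self.regions:
            prev = by_kind.get(r.kind)
            if prev is not None and r.start <= prev.end:
                raise InputError(
                    f"overlapping {r.kind!r} regions: [{prev.start},{prev.end}] "
                    f"and [{r.start},{r.end}]"
                )
            by_kind[r.kind] = r

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def to_mask(self, length: int) -> np.ndarray:
        """Boolean residue mask of size ``length`` (position 1 -> index 0)."""
        mask = np.zeros(length, dtype=bool)
        for r in self.regions:
            if r.end > length:
                raise InputError(f"region [{r.start},{r.end}] exceeds length {length}")
            mask[r.start - 1 : r.end] = True
        return mask


@dataclass
class CoordinateTrajectory:
    """Single-point (C-alpha level) coordinates per residue per frame, in A."""

    residue_ids: np.ndarray
    coords: np.ndarray  # (n_frames, n_residues, 3)

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must have shape (n_frames, n_residues, 3)")
        if self.coords.shape[1] != self.residue_ids.size:
            raise InputError("coords residue dimension does not match residue_ids")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


@dataclass
class FlexibilityProfile:
    """Latent per-residue flexibility in [0, 1] driving the synthetic model.

    ``planted_regions`` records deliberately planted high-flexibility blocks
    (ground truth for region-recovery checks); ordinary coil runs are flexible
    too but are not recorded here.
    """

    phi: np.ndarray
    planted_regions: RegionSet
    seed: int

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.size and (self.phi.min() < 0 or self.phi.max() > 1):
            raise InputError("phi must lie in [0, 1]")
        # planted blocks must sit inside the sequence
        for r in self.planted_regions:
            if r.end > self.phi.size:
                raise InputError(f"planted region [{r.start},{r.end}] outside sequence")

    def __len__(self) -> int:
        return self.phi.size
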