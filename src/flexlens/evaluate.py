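"""Per-residue, per-protein and per-bin evaluation of structure predictors.

The per-residue signal is a signed confidence: +max class probability where
the predicted label matches the reference label, -max class probability
where it does not.  Per-protein accuracy is the fraction of correctly
labelled residues, and bins of proteins are summarised by the mean accuracy
with a two-sided Student-t interval on the mean.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
from scipy import stats

from .content import q8_to_q3
from .errors import InputError, ParameterError
from .types import PredictionProfile


@dataclass
class SignedAccuracyProfile:
    """Signed per-residue confidence in [-1, 1]; sign encodes correctness."""

    residue_ids: np.ndarray
    signed_conf: np.ndarray
    correct: np.ndarray  # boolean
    scheme: str
    predictor_name: str


class BinStats(NamedTuple):
    mean: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class BinAccuracySummary:
    """Per-bin mean accuracy with confidence intervals, in bin order."""

    per_bin: dict[int, BinStats]
    ci_level: float


def _reference_in_scheme(ref_labels, scheme: str) -> np.ndarray:
    labels = np.asarray(list(ref_labels) if isinstance(ref_labels, str) else ref_labels,
                        dtype="<U1")
    if scheme.upper() == "Q3":
        return q8_to_q3(labels)
    return labels


def signed_confidence(pred: PredictionProfile, ref_labels) -> SignedAccuracyProfile:
    """Signed-confidence profile of ``pred`` against Q8 reference labels.

    The reference is collapsed to Q3 automatically when the prediction uses
    the three-state scheme (Q3 codes pass through the mapping unchanged).
    """
    ref = _reference_in_scheme(ref_labels, pred.scheme)
    if ref.size != len(pred):
        raise InputError(
            f"reference has {ref.size} residues but prediction has {len(pred)}"
        )
    correct = pred.predicted_labels == ref
    maxp = pred.probs.max(axis=1)
    signed = np.where(correct, maxp, -maxp)
    return SignedAccuracyProfile(
        residue_ids=np.arange(1, ref.size + 1),
        signed_conf=signed,
        correct=correct,
        scheme=pred.scheme,
        predictor_name=pred.predictor_name,
    )


def protein_accuracy(pred: PredictionProfile, ref_labels, mask=None) -> float:
    """Fraction of residues whose predicted label matches the reference.

    ``mask`` (boolean, True = comparable) excludes missing residues.
    """
    ref = _reference_in_scheme(ref_labels, pred.scheme)
    if ref.size != len(pred):
        raise InputError(
            f"reference has {ref.size} residues but prediction has {len(pred)}"
        )
    correct = pred.predicted_labels == ref
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != correct.size:
            raise InputError("mask length does not match residue count")
        correct = correct[mask]
    if correct.size == 0:
        raise InputError("no comparable residues")
    return float(correct.mean())


def bin_accuracy(
    accuracies: Mapping[str, float],
    bins,
    ci_level: float = 0.95,
) -> BinAccuracySummary:
    """Per-bin mean accuracy with a Student-t interval on the mean.

    ``bins`` is a :class:`flexlens.content.BinAssignment`.  Intervals are
    clipped to [0, 1]; a bin with a single protein reports a null interval
    with a warning.
    """
    if not 0 < ci_level < 1:
        raise ParameterError(f"ci_level must be in (0, 1), got {ci_level}")
    missing = set(accuracies) - set(bins.assignments)
    if missing:
        raise InputError(f"proteins without a bin: {sorted(missing)[:5]}")
    grouped: dict[int, list[float]] = {}
    for pid, acc in accuracies.items():
        grouped.setdefault(bins.assignments[pid], []).append(acc)

    per_bin: dict[int, BinStats] = {}
    for b in sorted(grouped):
        vals = np.array(grouped[b])
        mean = float(vals.mean())
        n = vals.size
        if n == 1:
            warnings.warn(
                f"bin {b} holds a single protein; interval undefined", stacklevel=2
            )
            per_bin[b] = BinStats(mean, float("nan"), float("nan"), n)
            continue
        sd = float(vals.std(ddof=1))
        tq = float(stats.t.ppf(0.5 + ci_level / 2, df=n - 1))
        half = tq * sd / np.sqrt(n)
        per_bin[b] = BinStats(
            mean, max(0.0, mean - half), min(1.0, mean + half), n
        )
    return BinAccuracySummary(per_bin=per_bin, ci_level=ci_level)
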