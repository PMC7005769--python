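"""Region-level concordance between flexibility, prediction error and disorder.

Per-residue profiles (longevity, signed confidence, disorder scores) are
turned into regions by thresholding an optionally smoothed profile, merging
runs separated by small gaps, and discarding short calls.  Consensus regions
require a minimum number of disorder predictors to agree; discordant regions
are flexible (low-longevity) regions with no disorder support — the signal
that disorder predictors miss dynamic regions which structure-predictor
error does flag.

Default thresholds (none of these is standardised in the field; all are
plain parameters): smoothing window 5, longevity threshold 0.2 (below),
signed-confidence threshold 0.0 (below), disorder threshold 0.5 with 2 of 3
predictors agreeing, minimum region length 3, merge gap 2, minimum overlap 1.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import InputError, ParameterError
from .types import DisorderProfile, Region, RegionSet

# Region kind tags
LOW_LONGEVITY = "low_longevity"
LOW_CONFIDENCE = "low_confidence"
DISORDER_CONSENSUS = "disorder_consensus"
DISCORDANT = "discordant"

DEFAULTS = {
    "smooth_window": 5,
    "longevity_threshold": 0.2,
    "confidence_threshold": 0.0,
    "disorder_threshold": 0.5,
    "consensus_k": 2,
    "min_len": 3,
    "merge_gap": 2,
    "min_overlap": 1,
}


def smooth(profile, window: int) -> np.ndarray:
    """Centered moving average; edges use truncated windows; window 1 = identity."""
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 1, got {window}")
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1:
        raise InputError("profile must be 1-D")
    if window == 1:
        return x.copy()
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based half-open (start, stop) spans of True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2], edges[1::2]))


def call_regions(
    profile,
    direction: str,
    threshold: float,
    min_len: int = 3,
    merge_gap: int = 2,
    smooth_window: int = 1,
    kind: str = "region",
    protein_id: str = "",
) -> RegionSet:
    """Call maximal regions where the (smoothed) profile crosses a threshold.

    ``direction='below'`` qualifies residues with smoothed value strictly
    below ``threshold``; ``'above'`` strictly above.  Qualifying runs
    separated by at most ``merge_gap`` residues are merged, then runs shorter
    than ``min_len`` are discarded.  Each region's score is the mean of the
    raw (unsmoothed) profile over the region.
    """
    if direction not in ("below", "above"):
        raise ParameterError(f"direction must be 'below' or 'above', got {direction!r}")
    if min_len < 1:
        raise ParameterError(f"min_len must be >= 1, got {min_len}")
    if merge_gap < 0:
        raise ParameterError(f"merge_gap must be >= 0, got {merge_gap}")
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    raw = np.asarray(profile, dtype=float)
    smoothed = smooth(raw, smooth_window)
    mask = smoothed < threshold if direction == "below" else smoothed > threshold

    spans = _mask_runs(mask)
    merged: list[list[int]] = []
    for start, stop in spans:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    regions = [
        Region(protein_id, s + 1, e, kind, float(raw[s:e].mean()))
        for s, e in merged
        if e - s >= min_len
    ]
    return RegionSet(regions)


def disorder_consensus(
    profiles: list[DisorderProfile],
    threshold: float = 0.5,
    k: int = 2,
    min_len: int = 3,
    merge_gap: int = 2,
    smooth_window: int = 1,
    protein_id: str = "",
) -> RegionSet:
    """Regions where at least ``k`` of the predictors score >= ``threshold``.

    The per-residue agreement count is region-called with direction 'above'
    at threshold k - 0.5, so a region requires >= k agreeing predictors.
    """
    if not profiles:
        raise InputError("at least one disorder profile is required")
    if not 1 <= k <= len(profiles):
        raise ParameterError(f"k={k} must be within 1..{len(profiles)} predictors")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise InputError(f"disorder profiles disagree in length: {sorted(lengths)}")
    counts = np.sum([p.scores >= threshold for p in profiles], axis=0).astype(float)
    return call_regions(
        counts,
        direction="above",
        threshold=k - 0.5,
        min_len=min_len,
        merge_gap=merge_gap,
        smooth_window=smooth_window,
        kind=DISORDER_CONSENSUS,
        protein_id=protein_id,
    )


def discordant_regions(
    low_longevity: RegionSet, disorder: RegionSet, min_overlap: int = 1
) -> RegionSet:
    """Low-longevity regions with no disorder region overlapping >= min_overlap.

    These are the flexible regions that no disorder call supports.
    """
    if min_overlap < 1:
        raise ParameterError(f"min_overlap must be >= 1, got {min_overlap}")
    out = []
    for r in low_longevity:
        if all(r.overlap(d) < min_overlap for d in disorder):
            out.append(Region(r.protein_id, r.start, r.end, DISCORDANT, r.score))
    return RegionSet(out)


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises :class:`InputError` when either input has zero variance (the
    correlation is undefined there).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise InputError("profiles must have equal length >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise InputError("Spearman correlation undefined for zero-variance input")
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho)


def region_jaccard(a: RegionSet, b: RegionSet, length: int) -> float:
    """Residue-level Jaccard index between two region sets."""
    ma = a.to_mask(length)
    mb = b.to_mask(length)
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ma, mb).sum() / union)
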