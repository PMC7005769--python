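"""Per-residue RMSF from coordinate trajectories, with rigid-body superposition.

RMSF_i = sqrt( mean over frames of ||x_i(t) - mean_i||^2 ), in Angstrom.
Frames may be superposed first (Kabsch least-squares fit with a determinant
sign correction so only proper rotations are used) to remove global rigid
motion; otherwise rigid tumbling inflates every residue's fluctuation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, InputError, ParameterError
from .types import CoordinateTrajectory


@dataclass
class RMSFProfile:
    residue_ids: np.ndarray
    rmsf: np.ndarray  # Angstrom, >= 0
    aligned: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue_id": self.residue_ids, "rmsf": self.rmsf})


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimally superpose ``mobile`` onto ``reference``.

    Returns ``(aligned_coords, rmsd)`` where the rotation is constrained to
    be proper (determinant +1) and the RMSD is the minimised value.
    Requires >= 3 non-collinear points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise InputError("mobile and reference must both have shape (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise AlignmentError(f"superposition needs >= 3 points, got {n}")
    mob_mean = mob.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    mob_c = mob - mob_mean
    ref_c = ref - ref_mean

    cov = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-9:  # collinear point set: rotation about the axis is free
        raise AlignmentError("degenerate (collinear) coordinates; rotation undefined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        raise AlignmentError("rank-deficient covariance; rotation undefined")
    correction = np.diag([1.0, 1.0, d])
    rot = vt.T @ correction @ u.T
    aligned = mob_c @ rot.T + ref_mean
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1))))
    return aligned, rmsd


def rmsf_profile(
    traj: CoordinateTrajectory, align: bool = True, reference: str = "mean"
) -> RMSFProfile:
    """Per-residue RMSF about the (optionally superposed) mean structure.

    With ``align=True`` every frame is superposed onto frame 0; with
    ``reference='mean'`` a single refinement pass re-superposes onto the
    resulting mean structure before fluctuations are measured.
    ``reference='frame0'`` skips the refinement pass.
    """
    if traj.n_frames < 2:
        raise InputError("RMSF needs at least 2 frames")
    if reference not in ("mean", "frame0"):
        raise ParameterError(f"reference must be 'mean' or 'frame0', got {reference!r}")
    coords = traj.coords
    if align:
        aligned = np.empty_like(coords)
        aligned[0] = coords[0]
        for t in range(1, traj.n_frames):
            aligned[t], _ = kabsch_superpose(coords[t], coords[0])
        if reference == "mean":
            mean = aligned.mean(axis=0)
            refined = np.empty_like(aligned)
            for t in range(traj.n_frames):
                refined[t], _ = kabsch_superpose(aligned[t], mean)
            aligned = refined
        coords = aligned
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    return RMSFProfile(residue_ids=traj.residue_ids.copy(), rmsf=rmsf, aligned=align)
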