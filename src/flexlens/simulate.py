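"""Synthetic inputs with the statistical structure the analysis assumes.

A latent per-residue flexibility profile phi in [0, 1] drives everything:

* the reference labels alternate coil and structured (helix/strand) runs
  with geometric run lengths; phi is ~0.9 on coil and planted flexible
  blocks, ~0.1 on structured runs, plus small uniform noise;
* the label trajectory flips residue i's state between consecutive frames
  with probability f_i = f_min + (f_max - f_min) * phi_i, resampling
  uniformly over the 7 other DSSP codes, so the expected run duration is
  1/f_i frames and longevity decreases with phi;
* structure predictors are correct with probability
  a_i = a_max - (a_max - a_min) * phi_i and concentrate probability mass
  q_i = 0.5 + conf_gain * (a_i - 0.5) on the emitted label, so both accuracy
  and confidence dip in flexible regions;
* disorder scores follow a logistic link on phi with Gaussian noise, except
  inside "blind" regions where the score is computed as if the residue were
  rigid — those become planted discordant regions;
* coordinates are an ideal helix-like mean curve plus isotropic Gaussian
  noise with per-residue amplitude sigma_i = sigma_min +
  (sigma_max - sigma_min) * phi_i (so RMSF_i = sigma_i * sqrt(3)), with an
  optional random rigid transform per frame to exercise superposition.

Every generator takes a single integer seed; independent sub-streams are
derived with fixed offsets, so a fixed seed gives bit-identical output.
Default rates are chosen so that, at the 200 ps frame spacing the
trajectory emulates, structured residues keep a DSSP label for tens of
nanoseconds while flexible residues flip every few nanoseconds, and
predictor accuracy spans roughly 0.4-0.97 across the flexibility range.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import expit

from .content import q8_to_q3
from .errors import ParameterError
from .types import (
    CoordinateTrajectory,
    DisorderProfile,
    FlexibilityProfile,
    LabelTrajectory,
    PredictionProfile,
    Q3_CODES,
    Q8_CODES,
    ReferenceStructure,
    Region,
    RegionSet,
    class_codes,
)

# Flexibility levels of the block-constant latent profile
PHI_FLEXIBLE = 0.9
PHI_ORDERED = 0.1
PHI_NOISE = 0.05

# Trajectory defaults: per-frame flip probabilities at phi=0 and phi=1.
# Structured residues then change label 2-3 times per 450-frame (90 ns)
# window (longevity ~0.35-0.45); flexible residues change every ~10 frames
# (longevity ~0.1).
DEFAULT_F_MIN = 0.001
DEFAULT_F_MAX = 0.022
DEFAULT_N_FRAMES = 1500
FRAME_SPACING_PS = 200.0

# Predictor defaults: near-ceiling per-residue accuracy on stably ordered
# residues, barely better than chance in fully flexible ones; per-protein
# accuracies then span roughly 0.6-0.9 across the order spectrum.
DEFAULT_A_MAX = 0.97
DEFAULT_A_MIN = 0.4
DEFAULT_CONF_GAIN = 0.9

# Disorder defaults
DEFAULT_SLOPE = 8.0
DEFAULT_NOISE_SD = 0.05

# Coordinate defaults (Angstrom)
DEFAULT_SIGMA_MIN = 0.5
DEFAULT_SIGMA_MAX = 3.0
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

PLANTED_KIND = "planted_flexible"


def _rng(seed: int, stream: int) -> np.random.Generator:
    if seed < 0:
        raise ParameterError(f"seed must be non-negative, got {seed}")
    return np.random.default_rng([int(seed), int(stream)])


def generate_reference(
    length: int = 200,
    helix_run_mean: float = 8.0,
    beta_run_mean: float = 6.0,
    coil_run_mean: float = 4.0,
    mix: tuple[float, float] = (0.6, 0.4),
    seed: int = 0,
    planted_blocks: int = 0,
    planted_block_len: int = 15,
    protein_id: str = "synth",
) -> tuple[ReferenceStructure, FlexibilityProfile]:
    """Reference labels as alternating coil/structured geometric runs.

    ``mix`` gives the (helix, strand) probabilities for each structured run.
    ``planted_blocks`` evenly spaced coil blocks of ``planted_block_len``
    residues are forced in and recorded as ground-truth flexible regions.
    """
    if length < 10:
        raise ParameterError(f"length must be >= 10, got {length}")
    for name, m in (("helix_run_mean", helix_run_mean),
                    ("beta_run_mean", beta_run_mean),
                    ("coil_run_mean", coil_run_mean)):
        if m < 1:
            raise ParameterError(f"{name} must be >= 1, got {m}")
    if abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
        raise ParameterError(f"mix must be non-negative and sum to 1, got {mix}")

    rng = _rng(seed, 0)
    labels: list[str] = []
    coil_turn = True
    while len(labels) < length:
        if coil_turn:
            n = int(rng.geometric(1.0 / coil_run_mean))
            labels.extend("C" * n)
        else:
            kind = "H" if rng.random() < mix[0] else "E"
            mean = helix_run_mean if kind == "H" else beta_run_mean
            labels.extend(kind * int(rng.geometric(1.0 / mean)))
        coil_turn = not coil_turn
    labels = labels[:length]

    planted: list[Region] = []
    if planted_blocks:
        if planted_blocks * planted_block_len > length:
            raise ParameterError("planted blocks do not fit in the sequence")
        gap = length // (planted_blocks + 1)
        for b in range(planted_blocks):
            s0 = min(max((b + 1) * gap - planted_block_len // 2, 0),
                     length - planted_block_len)
            labels[s0 : s0 + planted_block_len] = "C" * planted_block_len
            planted.append(Region(protein_id, s0 + 1, s0 + planted_block_len,
                                  PLANTED_KIND))

    lab = np.array(labels, dtype="<U1")
    phi = np.where(lab == "C", PHI_FLEXIBLE, PHI_ORDERED)
    phi = np.clip(phi + rng.uniform(-PHI_NOISE, PHI_NOISE, size=length), 0.0, 1.0)
    sequence = "".join(rng.choice(_AMINO_ACIDS, size=length))
    ref = ReferenceStructure(
        protein_id=protein_id,
        sequence=sequence,
        labels_q8="".join(labels),
        residue_ids=np.arange(1, length + 1),
    )
    flex = FlexibilityProfile(phi=phi, planted_regions=RegionSet(planted), seed=seed)
    return ref, flex


def generate_trajectory(
    ref: ReferenceStructure,
    flex: FlexibilityProfile,
    n_frames: int = DEFAULT_N_FRAMES,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    seed: int = 0,
) -> LabelTrajectory:
    """Markov label dynamics: flip with probability f(phi), resample among
    the 7 other codes.  Frame 0 is the reference; times step 200 ps."""
    if not 0 <= f_min <= f_max <= 1:
        raise ParameterError(f"need 0 <= f_min <= f_max <= 1, got {f_min}, {f_max}")
    if n_frames < 2:
        raise ParameterError(f"n_frames must be >= 2, got {n_frames}")
    if len(ref) != len(flex):
        raise ParameterError("reference and flexibility profile lengths differ")
    rng = _rng(seed, 1)
    n_res = len(ref)
    code_index = {c: i for i, c in enumerate(Q8_CODES)}
    cur = np.array([code_index[c] for c in ref.labels_q8], dtype=np.int64)
    f = f_min + (f_max - f_min) * flex.phi

    states = np.empty((n_frames, n_res), dtype=np.int64)
    states[0] = cur
    for t in range(1, n_frames):
        flips = rng.random(n_res) < f
        jumps = rng.integers(1, 8, size=n_res)  # 1..7: always a different code
        cur = np.where(flips, (cur + jumps) % 8, cur)
        states[t] = cur
    codes = np.array(Q8_CODES, dtype="<U1")
    return LabelTrajectory(
        residue_ids=ref.residue_ids.copy(),
        frame_times=FRAME_SPACING_PS * np.arange(n_frames, dtype=float),
        labels=codes[states],
    )


def generate_predictions(
    ref: ReferenceStructure,
    flex: FlexibilityProfile,
    a_max: float = DEFAULT_A_MAX,
    a_min: float = DEFAULT_A_MIN,
    conf_gain: float = DEFAULT_CONF_GAIN,
    scheme: str = "Q3",
    seed: int = 0,
    predictor_name: str = "synth-predictor",
) -> PredictionProfile:
    """Predictor output whose accuracy and confidence fall with flexibility."""
    if not 0 <= a_min <= a_max <= 1:
        raise ParameterError(f"need 0 <= a_min <= a_max <= 1, got {a_min}, {a_max}")
    if len(ref) != len(flex):
        raise ParameterError("reference and flexibility profile lengths differ")
    codes = class_codes(scheme)
    n_classes = len(codes)
    a = a_max - (a_max - a_min) * flex.phi
    q = 0.5 + conf_gain * (a - 0.5)
    if np.any(q <= 1.0 / n_classes) or np.any(q > 1.0):
        raise ParameterError(
            f"conf_gain={conf_gain} puts emitted-label mass outside "
            f"(1/{n_classes}, 1]"
        )
    ref_labels = q8_to_q3(ref.labels_q8) if scheme.upper() == "Q3" else ref.labels_q8
    code_index = {c: i for i, c in enumerate(codes)}
    ref_idx = np.array([code_index[c] for c in ref_labels], dtype=np.int64)

    rng = _rng(seed, 2)
    n_res = len(ref)
    correct = rng.random(n_res) < a
    offsets = rng.integers(1, n_classes, size=n_res)
    emit = np.where(correct, ref_idx, (ref_idx + offsets) % n_classes)

    probs = np.full((n_res, n_classes), ((1.0 - q) / (n_classes - 1))[:, None])
    probs[np.arange(n_res), emit] = q
    codes_arr = np.array(codes, dtype="<U1")
    return PredictionProfile(
        predictor_name=predictor_name,
        scheme=scheme,
        predicted_labels=codes_arr[emit],
        probs=probs,
    )


def generate_disorder(
    flex: FlexibilityProfile,
    n_predictors: int = 3,
    slope: float = DEFAULT_SLOPE,
    noise_sd: float = DEFAULT_NOISE_SD,
    blind_regions: RegionSet | None = None,
    seed: int = 0,
) -> list[DisorderProfile]:
    """Disorder scores tracking phi through a logistic link, with optional
    blind spots where every predictor scores the region as if rigid."""
    if n_predictors < 1:
        raise ParameterError(f"n_predictors must be >= 1, got {n_predictors}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    phi_eff = flex.phi.copy()
    if blind_regions is not None:
        for r in blind_regions:
            phi_eff[r.start - 1 : r.end] = PHI_ORDERED
    base = expit(slope * (phi_eff - 0.5))
    profiles = []
    for p in range(n_predictors):
        rng = _rng(seed, 10 + p)
        scores = np.clip(base + rng.normal(0.0, noise_sd, size=phi_eff.size), 0.0, 1.0)
        profiles.append(DisorderProfile(f"synth-disorder-{p + 1}", scores))
    return profiles


def generate_coordinates(
    flex,
    sigma_min: float = DEFAULT_SIGMA_MIN,
    sigma_max: float = DEFAULT_SIGMA_MAX,
    n_frames: int = DEFAULT_N_FRAMES,
    rigid_motion: bool = False,
    seed: int = 0,
) -> CoordinateTrajectory:
    """Helix-like mean curve plus isotropic Gaussian per-residue noise.

    ``flex`` may be a :class:`FlexibilityProfile` or a bare phi array.  The
    noise stream does not depend on ``rigid_motion``, so the same seed with
    and without rigid tumbling yields the same underlying fluctuations.
    """
    phi = np.asarray(
        flex.phi if isinstance(flex, FlexibilityProfile) else flex, dtype=float
    )
    if sigma_min > sigma_max or sigma_min < 0:
        raise ParameterError(f"need 0 <= sigma_min <= sigma_max, got {sigma_min}, {sigma_max}")
    if n_frames < 2:
        raise ParameterError(f"n_frames must be >= 2, got {n_frames}")
    n_res = phi.size
    idx = np.arange(n_res)
    theta = idx * (2.0 * np.pi / 3.6)  # 3.6 residues per helical turn
    mean = np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * idx],
        axis=1,
    )
    sigma = sigma_min + (sigma_max - sigma_min) * phi
    rng_noise = _rng(seed, 20)
    coords = mean[None] + rng_noise.normal(size=(n_frames, n_res, 3)) * sigma[None, :, None]
    if rigid_motion:
        rng_rigid = _rng(seed, 21)
        rots = Rotation.random(n_frames, rng=rng_rigid)
        shifts = rng_rigid.uniform(-20.0, 20.0, size=(n_frames, 3))
        for t in range(n_frames):
            coords[t] = coords[t] @ rots[t].as_matrix().T + shifts[t]
    return CoordinateTrajectory(residue_ids=np.arange(1, n_res + 1), coords=coords)


# ---------------------------------------------------------------------------
# Study scenarios
# ---------------------------------------------------------------------------

@dataclass
class RecoveryScenario:
    """A protein with planted flexible blocks and one disorder blind spot."""

    ref: ReferenceStructure
    flex: FlexibilityProfile
    traj: LabelTrajectory
    disorder: list[DisorderProfile]
    blind: RegionSet  # the planted block hidden from the disorder predictors


def region_recovery_scenario(
    seed: int = 0,
    length: int = 200,
    n_blocks: int = 3,
    block_len: int = 15,
    n_frames: int = DEFAULT_N_FRAMES,
) -> RecoveryScenario:
    """Fixed study conditions for region recovery: a mostly ordered chain
    (long structured runs, single-residue coil spacers) with ``n_blocks``
    planted flexible blocks; the last block is a disorder blind spot."""
    ref, flex = generate_reference(
        length=length,
        helix_run_mean=20.0,
        beta_run_mean=10.0,
        coil_run_mean=1.0,
        mix=(0.6, 0.4),
        seed=seed,
        planted_blocks=n_blocks,
        planted_block_len=block_len,
    )
    traj = generate_trajectory(ref, flex, n_frames=n_frames, seed=seed)
    blind = RegionSet([flex.planted_regions.regions[-1]])
    disorder = generate_disorder(flex, blind_regions=blind, seed=seed)
    return RecoveryScenario(ref=ref, flex=flex, traj=traj, disorder=disorder, blind=blind)


def ordered_population(
    n_proteins: int = 100, seed: int = 0
) -> list[tuple[ReferenceStructure, FlexibilityProfile]]:
    """A population spanning the order spectrum: protein j's coil runs grow
    and its structured runs shrink with j, with chain lengths 200 +/- 20."""
    if n_proteins < 2:
        raise ParameterError(f"n_proteins must be >= 2, got {n_proteins}")
    rng = _rng(seed, 30)
    population = []
    for j in range(n_proteins):
        t = j / (n_proteins - 1)
        length = int(rng.integers(180, 221))
        sub_seed = int((seed * 100003 + j + 1) % 2**31)
        ref, flex = generate_reference(
            length=length,
            helix_run_mean=12.0 - 8.0 * t,
            beta_run_mean=8.0 - 5.0 * t,
            coil_run_mean=1.0 + 7.0 * t,
            mix=(0.6, 0.4),
            seed=sub_seed,
            protein_id=f"synth-{j:03d}",
        )
        population.append((ref, flex))
    return population
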