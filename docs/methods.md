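# Methods

This note records the models and procedures flexlens implements, the
parameters that matter, how the synthetic-data generator is calibrated, the
numerical choices, and what the tests do and do not demonstrate.

## Structural longevity

The input is a frames × residues matrix of eight-state DSSP codes
(H, G, I, E, B, T, S, C), sampled from a simulation at regular intervals
(the trajectories this package emulates store a frame every 200 ps).
Analysis is restricted by default to the trailing 30% of frames
(`select_window`, floor rule on the frame count) — the equilibrated tail of
a run, e.g. the last 300 ns of 1 µs.  For one residue the label series is
split into maximal constant runs ℓ₁…ℓ_R and scored by one of three modes:

* **mean** (default): `(Σℓ/R)/N = 1/R`.  Exactly 1 for a constant label
  and 1/N for a label flipping every frame; bounded in `[1/N, 1]` with
  equality at 1 iff R = 1.
* **weighted**: `(Σℓ²/Σℓ)/N` — the expected length of the run containing a
  uniformly chosen frame, divided by N.  Always ≥ the mean mode
  (length-biased sampling inequality).
* **exp**: `Σ(bˡ − 1)/(bᴺ − 1)` with base b > 1 (default 2), rewarding long
  uninterrupted runs far more than many short ones.  Computed in log space;
  note that with the `bᴺ − 1` normaliser any residue whose longest run is
  much shorter than N scores vanishingly small (it may underflow to exactly
  0 at N ≈ 1500), while a constant residue still scores exactly 1.  The
  mean mode is the default because it is the interpretable statistic; the
  exp mode exists for analyses that want run-length emphasis.

Missing residues are excluded, never imputed: run statistics are computed
only for residues present in the trajectory.

## Ordered-content score and binning

Q8 labels collapse to three states (H,G,I → helix; E,B → strand; T,S,C →
coil), so that 3₁₀/α/π stretches concatenate into single helix runs.  Each
helix or strand run of length ℓ contributes `base^ℓ` (base 2 by default —
the exponential emphasises uninterrupted ordered stretches; the base is a
free parameter because the scale of the score is arbitrary units), and the
sum is divided by chain length.  Note one edge case: at base 2, merging two
length-1 runs leaves the raw score unchanged (2² = 2¹ + 2¹); consolidation
is strictly score-increasing whenever the merged run exceeds two residues.
Populations are split into K bins (default 5) at the k/K quantiles of the
normalised score, ties to the lower bin; fixed user-supplied edges are also
accepted since published bin boundaries are usually not recoverable.
A length filter (`center ± tol`, default 200 ± 20 residues) reproduces the
chain-length windows such studies apply.

## Predictor evaluation

Predictions carry a label and a class-probability vector per residue
(probability columns in fixed class order: C,H,E for three-state tables,
H,G,I,E,B,T,S,C for eight-state).  The signed confidence at a residue is
`+max(p)` if the predicted label equals the reference (DSSP) label and
`−max(p)` otherwise; reference labels are collapsed to Q3 automatically
when the prediction is three-state.  Because the Q8→Q3 map is many-to-one,
Q8-correct implies Q3-correct, hence Q3 accuracy ≥ Q8 accuracy for the same
prediction — a property the tests check exactly.  Per-protein accuracy is
residue-averaged; per-bin summaries average protein accuracies (not pooled
residues) and report a two-sided Student-t interval on the mean (default
level 0.95), clipped to [0, 1]; a single-protein bin reports a null
interval with a warning.

## RMSF and superposition

`RMSF_i = sqrt(mean_t ‖x_i(t) − x̄_i‖²)` over single-point (Cα-level)
coordinates.  Optional alignment removes global rigid motion: every frame
is superposed onto frame 0 by the Kabsch least-squares fit (SVD of the
covariance with a determinant sign correction so reflections are never
used), the mean structure is formed, and one refinement pass re-superposes
every frame onto that mean.  Full iterative convergence changes values
negligibly at these noise levels, so a single pass is the default;
frame-0-only alignment is exposed as an option.  Superposition requires at
least three non-collinear points (degenerate covariance raises an error);
weights are uniform.  For isotropic Gaussian noise of per-axis amplitude σ,
`RMSF = σ√3` — the closed form the tests use as an oracle.

## Region calling and concordance

Profiles are smoothed with a centred moving average (default window 5,
truncated at the edges), thresholded (strict inequality; direction `below`
for longevity and signed confidence, `above` for disorder-agreement
counts), runs separated by ≤ `merge_gap` (default 2) residues are merged,
and runs shorter than `min_len` (default 3) are discarded.  Region scores
are means of the raw profile.  Disorder consensus counts predictors with
score ≥ 0.5 per residue and calls regions where ≥ k (default 2 of 3)
agree.  Discordant regions are low-longevity regions whose overlap with
every disorder region is below `min_overlap` (default 1, i.e. zero overlap
required).  None of these thresholds is standardised anywhere — "peak" and
"band" are visual notions in the literature — so all are declared
configuration with the defaults above.  Rank concordance between profiles
is Spearman's ρ with average ranks for ties; zero-variance input is an
error, not a NaN.

Coordinates are 1-based inclusive in memory; BED-style output is 0-based
half-open.

## The synthetic-data generator

A latent per-residue flexibility φ ∈ [0, 1] drives every generated input,
so the statistical links the analysis assumes exist by construction and
their strength is controlled:

* **Reference**: alternating coil/structured runs with geometric lengths
  (defaults: helix mean 8, strand mean 6, coil mean 4, helix:strand mix
  0.6:0.4, length 200 — chain lengths in the population scenario are drawn
  from 180–220).  φ is 0.9 on coil and planted blocks, 0.1 on structured
  runs, plus uniform ±0.05 noise — block-constant so planted regions have
  crisp boundaries for recovery tests.  Optional planted flexible blocks
  (forced coil, recorded as ground truth) support region-recovery
  scenarios.
* **Label dynamics**: residue i flips with per-frame probability
  `f_i = f_min + (f_max − f_min)·φ_i`, resampling uniformly over the 7
  other codes (so the expected run length is exactly 1/f frames, and at
  f = 1 every run is one frame long).  Defaults f_min = 0.001,
  f_max = 0.022: at the 200 ps frame spacing, structured residues change
  label 2–3 times per 90 ns window (longevity ≈ 0.35–0.45) while flexible
  residues change every ~2 ns (longevity ≈ 0.1).  This is the regime in
  which the default call threshold of 0.2 separates the two populations
  under window-5 smoothing; the calibration must account for the full
  distribution of 1/R (not just 1/E[R]) because the run count R has
  binomial spread and 1/R a heavy lower tail.
* **Predictions**: correct with probability
  `a_i = a_max − (a_max − a_min)·φ_i`; wrong labels uniform over the rest;
  the emitted label carries probability mass `q_i = 0.5 + g·(a_i − 0.5)`
  (errors if q leaves (1/n_classes, 1]).  Defaults a_max = 0.97,
  a_min = 0.4, g = 0.9: near-ceiling accuracy on stably ordered residues,
  barely above chance in fully flexible ones.  Per-protein accuracies then
  span ≈ 0.62–0.91 across the order spectrum, and per-residue signed
  confidence correlates with longevity at ρ ≈ +0.65 — the per-residue
  Bernoulli correctness noise caps this correlation, which is why the
  accuracy contrast is set this wide.
* **Disorder**: `logistic(slope·(φ − 0.5))` (slope 8) plus Gaussian noise
  (sd 0.05), clipped to [0, 1]; each predictor gets an independent noise
  stream.  Inside declared blind regions the score is computed as if
  φ = 0.1 — these become the planted discordant regions.
* **Coordinates**: an ideal helix-like mean curve (rise 1.5 Å, radius
  2.3 Å, 3.6 residues/turn) plus isotropic Gaussian noise with
  `σ_i = σ_min + (σ_max − σ_min)·φ_i` (defaults 0.5–3 Å, a realistic Cα
  RMSF span); optional random per-frame rigid transforms exercise the
  superposition path.  The noise stream is independent of the rigid-motion
  flag, so aligned RMSF with and without tumbling can be compared exactly.

Sub-streams are derived from a single integer seed with fixed offsets
(numpy `default_rng([seed, stream])`), so fixed seeds give bit-identical
output and predictors/frames never share a stream.

**Study scenarios.**  `region_recovery_scenario` uses a mostly ordered
chain (helix run mean 20, strand 10, coil 1 — so flexible spacers are
single residues below the minimum call length) with three planted
15-residue flexible blocks, the last hidden from the disorder predictors;
these conditions give the region caller crisp targets while leaving
realistic single-residue flexible noise.  `ordered_population` spans the
order spectrum by sliding the run-length means across 100 proteins.  Note
that the rank-correlation invariants are checked on balanced conditions
(the default run-length mixture, or long chains): on the mostly-ordered
recovery chain only ~20% of residues are flexible, which caps the
attainable two-group rank correlation regardless of signal quality.

**What the generator does not emulate**: real DSSP transition structure
(flips are uniform over the other 7 codes), amino-acid composition biases
of disordered sequences, anisotropic or correlated coordinate fluctuations,
predictor-specific error structure, or cooperative (whole-segment)
unfolding.  Passing tests therefore demonstrate that the statistics recover
the planted structure under the assumed monotone links — not that any real
predictor or force field behaves this way.

## Numerical choices

* Exp-mode longevity in log space (`logsumexp`); underflow to 0 is accepted
  and documented rather than rescaled.
* Argmax ties in probability vectors resolve to the first class in the
  fixed class order; readers keep a file's label on argmax disagreement and
  warn rather than fail; rows summing to within [0.99, 1.01] are
  renormalised, anything else is a format error.
* Quantile bin edges use numpy's default (linear) quantiles; values equal
  to an edge fall in the lower bin; an all-tied population lands in bin 1
  with a warning.
* Student-t intervals are clipped to [0, 1] for reporting.
* Kabsch degeneracy: second singular value below 1e-9 of the first (or a
  zero determinant) raises an alignment error.
* Coordinate tables are written at %.17g and parsed with round-trip float
  precision, so write→read is exact.

## Problem sizes in the default test run

The suite checks the closed-form RMSF at 5,000 frames × 60 residues, rank
recovery at 200 residues × 1,500 frames, the run-count oracle on 1,000
random matrices, calibration checks at 10,000 residues, and the
rank-correlation invariant at 4,000 residues × 600 frames; the full run
takes well under a minute on one core.

## Known limitations

* Longevity treats the label alphabet as unordered: a coil↔turn flicker
  counts the same as helix↔strand, although the former is often considered
  "still coil" in three-state terms.  Computing longevity on Q3-collapsed
  trajectories is possible by mapping labels before building the matrix,
  but is not a built-in mode.
* The discordance call is descriptive — no permutation test accompanies the
  overlap statement.
* Disorder inputs must arrive pre-normalised to [0, 1]; no per-predictor
  calibration is applied.
* Binary trajectory formats (XTC/DCD), PDB/mmCIF atomic records, and
  running DSSP itself are out of scope; the package consumes already
  assigned labels and extracted coordinates.
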