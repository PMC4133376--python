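# Methods

This note documents the models, algorithmic choices and default parameters
of `rivaldec`, and what the synthetic-data studies do and do not show.

## Paradigms and time conventions

Two block designs are modeled.  The binocular non-rivalry (BNR) localizer:
5 face and 5 house blocks alternating, each followed by a rest block, all
30 s, TR 3 s, 200 volumes.  The binocular rivalry (BR) run: 15 picture and
15 rest blocks of 20 s, TR 1 s, 600 volumes, of which 300 are
picture-block ("task") time points.  Volumes are 0-based and cover
half-open intervals `[t·TR, (t+1)·TR)`; a block-boundary instant belongs to
the block that starts there, which makes the tiling unambiguous.

Behavioral button presses are converted to a per-task-volume percept
vector by carrying the most recent report forward.  Task volumes before
the first report are labeled `unknown` and excluded from scoring (the
original protocol does not state how they were handled; exclusion is the
conservative choice).  No reaction-time correction is applied — report
latency is an acknowledged limitation of the behavioral reference.
Dominance phases are the intervals between consecutive reports clipped to
picture blocks, so a percept spanning a rest break counts once per block.
Group statistics over subjects use the mean of per-subject phase-duration
means and the n−1 sample SD across those means.  For the reference
ten-subject data (`rivaldec.datasets`) this yields 3.37 s ± 0.93 s; note
the per-subject means span 1.78–4.6 s (the package reports the true range
of its inputs).

## Synthetic data generator

`simgen` emulates the statistical structure the pipeline assumes, not MR
physics.  On a 20×20×30 voxel grid (3 mm isotropic; the BR acquisition
covers the central 16 slices) five disjoint regions are planted: bilateral
FFA and one OFA preferring faces, bilateral PPA preferring houses, with
peak response amplitudes of 1.6–2 % of a 1000 a.u. baseline by default.
Each voxel's signal is

    baseline × (1 + response/100) + drift + noise,

where the response is the preferred-condition boxcar (BNR) or the
conscious-percept indicator restricted to picture blocks (BR), convolved
with a peak-normalized double-gamma HRF (peak ≈ 5 s, undershoot ≈ 15 s).
Drift is a low-order polynomial in normalized time (default quadratic,
3 a.u.).  Noise has two components: i.i.d. Gaussian per voxel per volume
(default SD 1 % of baseline) and a region-coherent term shared by all
voxels of a region (default SD 0.5 %), i.i.d. over time.  The coherent
term represents spontaneous within-region BOLD fluctuations; without it
the ROI mean of purely independent voxel noise shrinks as 1/√n_vox and
rest-block signals become unrealistically quiet — in particular the
reliability protocol's rest-block control would never cross the
assignment margin.  Temporal autocorrelation of noise is not modeled (the
decoding chain nowhere exploits or corrects it); neither are motion,
slice-timing offsets, or mixed/piecemeal percepts.

Rivalry dominance phases are i.i.d. gamma (default mean 3.4 s, shape 3 —
right-skewed and positive, as rivalry phase distributions are), strictly
alternating, truncated to tile the 300 s of picture time; the first
percept is a fair coin.  The behavioral log contains one event per phase
onset, optionally delayed by a configurable reaction time (default 0).
A subject who does not experience rivalry can be emulated
(`br_percept_locked=False`): the BR-run regional signal is then not
driven by the percept at all while behavior is still logged.

Because the planted effects are clean, block-locked and stationary,
passing results on synthetic subjects demonstrate the pipeline's
correctness and internal consistency — not performance on real scanner
data, whose artifacts (motion, physiological cycles, field
inhomogeneity) are out of scope here.

## Localizer

Smoothing: per-volume isotropic Gaussian, σ = FWHM/(2√(2 ln 2)) in voxel
units, nearest-edge boundary handling, default FWHM 5 mm.  GLM: voxelwise
OLS against [face ⊗ HRF, house ⊗ HRF, intercept, linear drift]; the drift
regressor stands in for a high-pass filter.  t statistics use
c'β̂ / √(σ̂² c'(X'X)⁻¹c) with dof = T − 4.

Family-wise error control is **Bonferroni** over in-mask voxels rather
than random-field theory: RFT's smoothness estimation is out of
proportion for this re-implementation, and Bonferroni is conservative and
exactly testable.  p-values are one-sided (the contrasts are
directional).  FDR fallback is Benjamini–Hochberg.  Clusters use
6-connectivity (strictest standard choice), minimum size 5; ties in peak
t break by larger size, then lexicographic peak coordinate.  The analysis
mask is the BR acquisition's slice coverage (central 16 slices by
default), so every selected ROI is measurable in the rivalry run.  ROI
selection: top 3 per contrast by peak t; a subject failing to yield ≥ 1
face-contrast and ≥ 2 house-contrast ROIs at FWE is retried at FDR and
otherwise excluded, mirroring the reference protocol's first exclusion.
For decoding, ROIs are ordered so every prefix is usable: best face ROI,
best two house ROIs, then the remainder by peak t (the "3/4/5 ROI"
ablation uses these prefixes).

## Signal preparation

Order of operations (identical for both runs except where noted):
cubic polynomial detrend of each ROI voxel and of the whole-brain mean;
(BR only) k-means with k = 2 on the detrended, mean-centered voxel time
courses of each ROI, Lloyd's algorithm with 10 seeded restarts; ROI
averaging over retained voxels; percent signal change (PSC); subtraction
of the whole-brain PSC; hemodynamic realignment; rest-point removal;
quadratic detrend of the concatenated task segment (and of the rest
segment, which is processed identically to serve as the control).

Two points deserve explanation:

- **Which k-means cluster is kept.**  The retained cluster is the one
  whose centroid correlates best (|r|) with the ROI's mean time course —
  the coherent, task-participating ensemble; the alternative rule (keep
  the higher-variance cluster) favors exactly the noisy voxels the step
  exists to remove.  At least one voxel is always retained, and an ROI of
  identical voxels is kept whole with a warning.
- **Detrending vs percent signal change.**  The full-series cubic detrend
  inside the chain preserves the temporal mean (residuals plus original
  mean), because PSC immediately downstream divides by that mean.  The
  standalone `detrend_poly` returns plain residuals (a constant series
  detrends to zero); `keep_mean=True` selects the chain behavior.  This
  also gives the chain its scale-invariance: multiplying all raw
  intensities by c > 0 leaves the final matrix unchanged.

The hemodynamic realignment advances the signal by
`round(delay/TR)` samples (`out[t] = in[t+s]`), so the lagged BOLD
response lines up with the stimulus/percept labels of its cause; trailing
samples replicate the last value to avoid injecting zeros into PSC units.
The delay default is 6 s (the canonical HRF peak region), i.e. 2 volumes
for the localizer and 6 for the rivalry run.  The whole-brain mean is
inclusive (ROI voxels are not excluded from it); with ROIs occupying ~1 %
of the grid the distinction is negligible.

## Network and decoding

Architecture: inputs (one per ROI) → 65 logistic hidden units → 2
logistic outputs; one-hot targets use exact 0/1.  Initialization: weights
uniform in ±1/√fan_in, biases zero, seeded.  Training: full-batch
gradient descent on the mean squared error over a random 75 %/25 %
train/validation split (re-randomized on every restart), fixed learning
rate 0.05, keeping the weights at the minimum of the validation MSE.  The
epoch budget is 8000: at this operating point validation MSE on
well-localized synthetic subjects settles well below the 0.02 acceptance
threshold (typically 0.0002–0.01) and the fraction of
rivalry points failing the 0.9 assignment margin lands at 10–16 %,
consistent with the reference experiment's 10.7 ± 3.7 %; a much shorter
budget leaves the output layer insufficiently saturated and inflates the
unassigned fraction.  An adaptive step-size variant (×1.05 on
improvement, ×0.7 on regression) is available but off by default, keeping
plain gradient descent the canonical path.  Restarts (fresh seed, fresh
split; cap 20) repeat training until validation MSE < 0.02; the decode
loop (cap 50) repeats train+classify until < 16.7 % of rivalry points are
unassigned.  Both caps turn non-convergence into a reported outcome
(`ConvergenceError` carrying the best attempt) rather than a hang.  Both
thresholds are compared strictly (`>` 0.9, `<` 16.7 %), as specified.
Inputs receive no standardization beyond the preparation chain — its
columns are already zero-mean percent-change residuals, and z-scoring
would alter the method.  The training loop is numba-compiled; the pure
NumPy gradient implementation is retained and is verified against central
finite differences (and against one compiled step) in the test suite.

## Scoring and reliability

Success is counted over assigned points with known behavioral labels;
the discard rate counts unassigned points over all 300 task points.  The
binomial test is the exact one-sided tail P(X ≥ k | n, ½), computed with
integer arithmetic (this reproduces the reference subject-1 value 0.004;
a two-sided test gives ≈ 0.007 and does not).

Reliability: the train+classify procedure is repeated n times (1000 in
the original protocol; the package's studies use 150–200, which estimate
the distribution moments well within the stochastic tolerances involved)
on the task inputs, and independently on the rest-block control, each
repetition recording the house percentage of assigned points.
Repetitions are *not* gated on the 16.7 % unassigned rule: the control
arm could never satisfy it, and the collected quantity is the assigned
house fraction regardless.  Failed repetitions (no assigned points or
training non-convergence) are counted and excluded, with an abort above
10 % failures.  Distribution statistics are sample mean, n−1 variance,
skewness, Fisher excess kurtosis (normal ⇒ 0; "leptokurtic" ⇒ > 0) and
the Shapiro–Wilk p-value.

The four-condition verdict for trusting a decoder output: (1) ≥ 3 ROIs
localized; (2) accepted validation MSE < 0.02; (3) task-arm mean house %
in [25, 75] and excess kurtosis > 0 or Shapiro p > 0.05; (4) task-arm
variance and |skewness| both strictly smaller than the rest arm's.  On
near-ceiling synthetic subjects condition 4's skewness clause is the
fragile one: the task distribution is extremely tight (variance well
under 1 percentage point²) and sits on a floor — most repetitions decode
identically and deviations point toward 50 % — so its sample skewness can
rival the control's for some subjects even when every other margin is
wide.  Real data, operating far from ceiling, does not concentrate this
way.  This is a known limitation of the verdict on idealized data, not of
the implementation.

## Problem sizes of the packaged studies

The packaged tests and the acceptance script use: 10 synthetic subjects
for the cohort decode; 200 repetitions (tests) or 150 (script) per
reliability arm; 1000 null voxels for GLM type-I calibration.  These
sizes were chosen to estimate each quantity comfortably within its
stochastic tolerance while keeping a full run desk-scale.
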