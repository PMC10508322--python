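# Methods

## Overview

`boldvar` implements an individual-differences analysis linking the
temporal variability of the resting-state BOLD signal to behavioral
measures. The pipeline has five analytic stages:

1. **Variability maps.** Each subject's denoised 4D resting scan is
   rescaled so the mean over all in-brain voxels and timepoints is 100
   ("grand-mean-100" normalization), and the per-voxel temporal standard
   deviation (BOLD-SD) is computed. The mean square successive difference
   (MSSD) — the mean of squared differences between consecutive
   timepoints, the classical von Neumann statistic, with no division by
   two and no square root — is available as an alternative metric; across
   voxels the two are very highly correlated on realistic data.
2. **Stacking.** Subject maps are stacked into a subjects × voxels matrix
   over a common mask (the intersection of subject masks unless a study
   mask is supplied), with a recorded C-order voxel linearization.
3. **Confound residualization.** Age and mean framewise displacement (FD)
   are regressed out of every voxel column, and age out of every
   behavioral measure, by ordinary least squares on an intercept plus all
   confounds jointly. Joint entry is order-invariant and spans the same
   space as sequential single-confound regressions. Residualization is a
   projection: idempotent, residuals exactly orthogonal to the confound
   design. An `adjust=off` path removes only FD from the brain block and
   leaves behavior untouched, the preprocessing used for an
   age-unadjusted younger-subsample analysis. Missing behavioral values
   are an error, never imputed.
4. **Behavioral PLS.** The measures × voxels cross-block matrix R holds
   Pearson correlations across subjects (both blocks column-standardized;
   a raw-covariance mode is a config switch — correlation is the
   behavioral-PLS toolbox convention, "covariance" the looser common
   description). The SVD R = U S Vᵀ yields latent variables (LVs):
   behavior saliences U, voxel saliences V, and singular values whose
   normalized squares s_k²/Σs_j² are the covariance fraction each LV
   explains (always reported over all min(measures, voxels) LVs).
   Brain scores are the standardized brain rows projected onto V.
5. **Inference and reporting.** Permutation test: behavior rows permuted
   relative to brain rows, k-th permuted singular value compared with the
   k-th observed, p_k = (exceedances+1)/(N+1) — the floor at N = 1000 is
   1/1001 ≈ 0.001, and no Procrustes rotation is applied in the
   permutation loop. Bootstrap: subjects resampled with replacement, the
   whole pipeline recomputed per resample, resampled saliences aligned to
   the original by the sign of the per-LV dot product (full orthogonal
   Procrustes alignment is available as an option; neither convention is
   asserted to be the original toolbox's). The bootstrap ratio
   BSR = salience / bootstrap SE is a t-like stability statistic;
   brain-score/behavior correlations get percentile CIs, and a
   correlation is flagged *robust* when its CI excludes zero. BSR maps
   are thresholded at |BSR| ≥ 2.5 with a 15-voxel cluster-extent minimum;
   connected components use 26-connectivity by default (6/18 available —
   the choice changes cluster counts and is therefore exposed), positive
   and negative voxels never merge, and per-network overlap is the
   proportion of each atlas network's voxels that are significant.

## Determinism

All randomness flows from one user seed through
`numpy.random.SeedSequence` spawning (one stream for permutations, one
for bootstrap), so repeated runs are bit-identical. The SVD sign
ambiguity is resolved by making each LV's largest-magnitude behavior
salience positive.

## Synthetic data generator

The generator emulates the study conditions: by default 157 subjects,
297 timepoints, 22 behavioral measures on their native scales
(T-score-like mean 50 / SD 10), ages uniform on 20–86 years, mean FD
log-normal around 0.15 mm. Brain (subjects × voxels SD values) and
behavior blocks are coupled through r standardized latent score vectors;
a `signal_voxel_fraction` of voxels carries the planted voxel-salience
pattern. Emitted time series are AR(1) (default coefficient 0.3, in the
range typical of denoised BOLD) and are rescaled post hoc so each
voxel's sample SD equals its target *exactly*, which makes downstream
oracle tests exact rather than asymptotic.

Design choices worth knowing:

- **Planted patterns are equal-magnitude random-sign loadings**
  (±1/√m on the support), not Gaussian. Correlation-mode PLS
  standardizes each voxel, which attenuates large loadings nonlinearly
  (in the strong-signal limit a Gaussian pattern can be recovered only
  up to corr ≈ √(2/π) ≈ 0.80); equal magnitudes keep the per-element
  signal-to-noise ratio uniform so parameter recovery measures the
  pipeline, not the attenuation artifact. Columns are exactly unit norm;
  for rank > 1 they are orthogonal in expectation only.
- **`effect_size` is a per-element signal-to-noise ratio.** The latent
  term is scaled by √(support size) × noise SD, so effect_size ≈ the
  ratio of latent-driven variation to noise at a single signal voxel
  (or behavior). Noise scales (`noise_sd` = 0.2 normalized-SD units,
  `behavior_noise_sd` = 1 z-unit, baseline voxel SD ≈ 1.5 with
  log-normal spread) are free parameters — the empirical voxelwise SD
  distribution of the study is not characterized — chosen once as
  plausible magnitudes.
- **Confounds contaminate both blocks** through per-column loadings
  drawn uniform on [0.5, 1.5]; a single strength parameter per confound
  is applied in normalized-SD units on the brain block and in T-score
  units (×10) on the behavior block so one value produces comparable
  relative contamination in both.
- SD values are clipped at zero (a standard deviation cannot be
  negative); with default scales clipping is essentially never active.

What the generator does *not* emulate: spatial autocorrelation and
anatomical structure, scanner drift and physiological noise, motion
artifacts, non-Gaussian behavioral distributions, and any relation
between the confounds and the latent scores beyond additive
contamination. Passing recovery tests therefore demonstrates the
correctness of the estimator and inference machinery under the stated
model, not robustness to realistic fMRI noise.

## Numerical choices and degenerate inputs

- Sample (n−1) denominators throughout: voxel SD, z-scores, column
  standardization, bootstrap SE. The SD denominator is exposed as
  config (`ddof`) because the original toolbox's convention is not
  documented.
- Grand-mean normalization averages in-mask voxels only (background air
  would otherwise dominate) and leaves out-of-mask voxels untouched;
  whole-volume normalization is available by passing a full mask.
- Zero-variance columns are an error with the offending column named;
  degenerate bootstrap resamples (zero-variance column after
  resampling) are redrawn and counted.
- A voxel whose salience does not vary across bootstrap resamples
  (SE = 0, e.g. noise-free planted data) gets a signed infinite BSR and
  a `stable_mask` flag instead of an overflow; thresholding treats it as
  supra-threshold.
- Permutation p-values use (k+1)/(N+1), never zero.
- Percentile bootstrap CIs undercover modestly at n ≈ 100 (~90%
  empirical coverage for a null-weight behavior at 95% nominal); the
  calibration test bounds coverage from below rather than asserting the
  nominal level. The CI is not recentered, so the point estimate is not
  guaranteed to lie inside it (only ci_low ≤ ci_high is guaranteed).
- The synchrony score reflects scan times (24 − t) *before* z-scoring,
  is bounded above by 1, unbounded below, and invariant to shifting all
  scan times by a constant. Scan midpoint is supplied as a 24-h decimal
  clock time; scanner logs are not parsed.

## Problem sizes

Validation runs at desk scale: permutation calibration uses 200 null
datasets (n = 60, 200 voxels, 8 measures, 200 permutations each);
parameter recovery uses n = 150 subjects, 2000 voxels and 1000
permutations; confound-removal uses 50 replicate datasets. These sizes
give binomial error bars tight enough for the stated bounds while
keeping the full suite in tens of seconds.

## Known limitations

- The deposited study data are required to reproduce the published
  covariance-explained figures; the package ships no subject data and
  `reproduce_published_analysis` expects a locally downloaded copy.
  Whether the deposit is pre- or post-residualization is not documented;
  both entry points exist (`adjust` on/off).
- One peak is reported per connected cluster; subdividing clusters by
  anatomical region requires supplying a label atlas.
- Anatomical region naming, surface rendering and figure generation are
  out of scope; outputs are TSV tables and NIfTI volumes.
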