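# boldvar

Resting-state BOLD signal variability and its relation to behavior.

`boldvar` is a pipeline for individual-differences neuroimaging: it
computes per-voxel temporal variability maps (BOLD-SD) from denoised 4D
resting fMRI, removes age and head-motion confounds, and relates the
variability maps to cognitive, socioemotional and chronotype measures
with **behavioral partial least squares (PLS)** — including permutation
tests of the latent variables, bootstrap-ratio (BSR) salience maps,
cluster-extent thresholding and network-overlap summaries. A
synthetic-data generator with planted latent structure lets every stage
be validated by parameter recovery.

## The model

For subject i, voxel v: after grand-mean-100 normalization of the scan,

    BOLD-SD(i, v) = sd over t of x_iv(t)        (sample, n−1 denominator)

Age and mean framewise displacement are residualized out of the
subjects × voxels matrix **X** (age alone out of the behavior matrix
**Y**) by OLS. Behavioral PLS decomposes the cross-block correlation
matrix

    R = corr(Y, X),     R = U S Vᵀ

into latent variables: behavior saliences **U**, voxel saliences **V**,
and singular values s_k with covariance explained s_k² / Σ_j s_j².
Significance of each LV comes from permuting behavior rows relative to
brain rows (p = (k+1)/(N+1) over N = 1000 permutations); voxel
reliability from 1000 bootstrap resamples via BSR = salience /
bootstrap SE, thresholded at |BSR| ≥ 2.5 with a 15-voxel cluster
minimum; and brain-score/behavior correlations get 95% percentile CIs,
flagged robust when the CI excludes zero.

Behavioral conventions: NIH-Toolbox-style fluid/crystallized composites
(mean 100/SD 15), 17 socioemotional T-scores (mean 50/SD 10), the
Morningness-Eveningness Questionnaire global score (16–86, with the
standard five chronotype categories), and a chronotype/test-time
synchrony score s = 1 − |z(MEQ) − z(24 − t_scan)|.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Simulate 157 subjects with one strongly planted brain–behavior latent
variable, then run the full PLS analysis:

```bash
boldvar simulate --n-subjects 157 --grid 8 8 8 --n-behaviors 8 \
    --latent-rank 1 --effect-size 3.0 --seed 11 --out demo
boldvar pls --sd-matrix demo/sd_matrix.npz --behavior demo/behavior.tsv \
    --n-perm 1000 --n-boot 1000 --seed 5 --out demo/results
```

prints

```
LV1: p = 0.000999, covariance explained = 99.8%
```

i.e. the planted latent variable is detected at the permutation floor
1/1001 and dominates the cross-block covariance. `demo/results/`
contains `lv_summary.tsv` (per-LV singular value, covariance explained,
permutation p), `behavior_correlations.tsv` — e.g.

```
measure      correlation  ci_low   ci_high  robust
measure_00   -0.944       -0.959   -0.924   True
measure_01    0.950        0.936    0.963   True
```

(each measure's correlation with the LV-1 brain scores, its bootstrap
CI, and the robustness flag), plus `clusters.tsv` (signed clusters with
peak coordinates and peak BSR) and the BSR/significance-mask NIfTI
volumes. The same analysis is available as a library
(`boldvar.run_behavioral_pls`) and through a YAML-configured
`boldvar run`, which also supports the age-unadjusted younger-subsample
variant (`subsample_age_below: 49`, `adjust: false`).

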