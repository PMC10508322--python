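"""Synthetic resting-state variability data with a planted latent structure.

The generator produces a subjects x voxels variability (SD) matrix and a
subjects x behaviors table coupled through a low-rank latent-variable
model, plus age and head-motion (mean FD) confounds that contaminate both
blocks.  Because the planted latent scores, voxel salience pattern and
behavior weights are returned alongside the data, every downstream stage
(residualization, PLS decomposition, permutation and bootstrap inference,
thresholding) can be validated by parameter recovery.

Model
-----
For subject i, voxel v and behavior b, with r planted latent variables:

    SD[i, v]   = baseline_v
               + effect_size * sigma_sd * sqrt(m) * sum_k Z[i,k] U[v,k]
               + age_c[i] * beta_age * a_v + fd_c[i] * beta_fd * f_v
               + eps,                eps ~ N(0, sigma_sd)

    B[i, b]    = 50 + 10 * ( effect_size * sqrt(p) * sum_k Z[i,k] W[b,k]
               + eta )               eta ~ N(0, sigma_beh)
               + age_c[i] * beta_age_beh * h_b + fd_c[i] * beta_fd_beh * g_b

where Z columns are standardized latent scores, U (voxels x r) and
W (behaviors x r) have unit-norm columns of equal-magnitude random-sign
loadings, U is supported on a random ``signal_voxel_fraction`` of voxels
(m of them), p is the number of behaviors, and age/FD enter through
per-column loadings drawn once per dataset.  The sqrt(m) / sqrt(p) factors make ``effect_size`` an
approximate per-element signal-to-noise ratio inside the signal support.
Behaviors are emitted on a T-score-like scale (mean 50, SD 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorTable
from .variability import SDMatrix, SubjectScan


@dataclass
class GeneratorConfig:
    """Study-condition parameters for one synthetic dataset.

    Defaults mirror the target study's conditions: 297 resting volumes,
    ages uniform over the sample's 20-86 year range, behaviors on the
    T-score scale.  ``effect_size`` is the ratio of latent-driven SD
    variation to the voxel noise SD; ``confound_strength_age`` /
    ``confound_strength_fd`` are slopes in normalized-SD units per year
    and per mm respectively.
    """

    n_subjects: int = 157
    grid_shape: tuple[int, int, int] = (10, 10, 10)
    n_timepoints: int = 297
    n_behaviors: int = 22
    latent_rank: int = 1
    signal_voxel_fraction: float = 0.25
    effect_size: float = 1.0
    ar_coefficient: float = 0.3
    confound_strength_age: float = 0.0
    confound_strength_fd: float = 0.0
    seed: int = 0
    # free noise/baseline scales (not calibrated to any empirical dataset):
    # baseline voxel SD ~1.5 normalized units with log-normal spread, voxel
    # noise sigma_sd, behavior noise sigma_beh in z-units.
    baseline_sd: float = 1.5
    noise_sd: float = 0.2
    behavior_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 1 or self.n_behaviors < 1:
            raise ValueError("counts must be >= 1")
        if self.latent_rank < 0:
            raise ValueError("latent_rank must be >= 0")
        if not 0 <= self.signal_voxel_fraction <= 1:
            raise ValueError("signal_voxel_fraction must lie in [0, 1]")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive ints")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class SyntheticTruth:
    """Ground truth planted by one generator run."""

    latent_scores: np.ndarray  # subjects x r, columns mean 0 / SD 1
    voxel_saliences_true: np.ndarray  # voxels x r, unit-norm columns
    behavior_weights_true: np.ndarray  # behaviors x r, unit-norm columns
    confound_coeffs: dict[str, np.ndarray | float] = field(default_factory=dict)
    target_sd_map: np.ndarray | None = None  # subjects x voxels
    age: np.ndarray | None = None
    mean_fd: np.ndarray | None = None

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            latent_scores=self.latent_scores,
            voxel_saliences_true=self.voxel_saliences_true,
            behavior_weights_true=self.behavior_weights_true,
            target_sd_map=self.target_sd_map,
            age=self.age,
            mean_fd=self.mean_fd,
            **{f"confound_{k}": np.asarray(v) for k, v in self.confound_coeffs.items()},
        )


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)


def _orthonormal_columns(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, r)))
    return q[:, :r]


def _sign_pattern_columns(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    """Unit-norm columns with equal-magnitude entries and random signs.

    Equal loading magnitudes keep the per-element signal-to-noise ratio
    uniform across the support, so the per-voxel standardization of
    correlation-mode PLS does not distort the planted pattern (Gaussian
    loadings would be shrunk nonlinearly at high effect size).  Columns are
    exactly unit norm; for rank > 1 they are orthogonal only in
    expectation (pairwise dot products are O(1/sqrt(n))).
    """
    return rng.choice([-1.0, 1.0], size=(n, r)) / np.sqrt(n)


def generate_dataset(
    config: GeneratorConfig,
    behavior_weights: np.ndarray | None = None,
    measure_names: list[str] | None = None,
) -> tuple[SDMatrix, BehaviorTable, SyntheticTruth]:
    """Generate one coupled (SD matrix, behavior table, truth) triple.

    ``behavior_weights`` optionally plants an explicit behaviors x rank
    weight pattern (columns are renormalized to unit length), e.g. to give
    positive-scale measures positive and cognitive measures negative
    loadings.  ``measure_names`` overrides the generic behavior column
    names.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, v, p, r = cfg.n_subjects, cfg.n_voxels, cfg.n_behaviors, cfg.latent_rank
    if r > min(p, v):
        raise ValueError(
            f"latent_rank={r} exceeds min(n_behaviors, n_voxels)={min(p, v)}"
        )
    if r > 0 and n < 3:
        raise ValueError("latent_rank > 0 needs n_subjects >= 3 to standardize scores")

    # planted structure
    if r > 0:
        latent = _standardize_columns(_orthonormal_columns(rng, n, r) if n > r else rng.standard_normal((n, r)))
        n_signal = max(r, int(round(cfg.signal_voxel_fraction * v)))
        support = rng.choice(v, size=n_signal, replace=False)
        u = np.zeros((v, r))
        u[support] = _sign_pattern_columns(rng, n_signal, r)
        if behavior_weights is not None:
            w = np.asarray(behavior_weights, dtype=float).reshape(p, r)
            w = w / np.linalg.norm(w, axis=0)
        else:
            w = _sign_pattern_columns(rng, p, r)
    else:
        latent = np.zeros((n, 0))
        n_signal = 0
        u = np.zeros((v, 0))
        w = np.zeros((p, 0))

    # confounds: age uniform over the sample's 20-86 range; FD log-normal
    # around a plausible ~0.15 mm median
    age = rng.uniform(20.0, 86.0, size=n)
    mean_fd = rng.lognormal(mean=np.log(0.15), sigma=0.4, size=n)
    age_c = age - age.mean()
    fd_c = mean_fd - mean_fd.mean()
    voxel_age_load = rng.uniform(0.5, 1.5, size=v)
    voxel_fd_load = rng.uniform(0.5, 1.5, size=v)
    beh_age_load = rng.uniform(0.5, 1.5, size=p)
    beh_fd_load = rng.uniform(0.5, 1.5, size=p)

    # brain block
    baseline = cfg.baseline_sd * rng.lognormal(mean=0.0, sigma=0.2, size=v)
    sd = np.tile(baseline, (n, 1))
    if r > 0:
        sd += cfg.effect_size * cfg.noise_sd * np.sqrt(n_signal) * (latent @ u.T)
    sd += cfg.noise_sd * rng.standard_normal((n, v))
    sd += age_c[:, None] * cfg.confound_strength_age * voxel_age_load[None, :]
    sd += fd_c[:, None] * cfg.confound_strength_fd * voxel_fd_load[None, :]
    np.maximum(sd, 0.0, out=sd)  # SD values cannot be negative

    # behavior block, T-score-like scale
    beh = np.zeros((n, p))
    if r > 0:
        beh += cfg.effect_size * np.sqrt(p) * (latent @ w.T)
    beh += cfg.behavior_noise_sd * rng.standard_normal((n, p))
    beh = 50.0 + 10.0 * beh
    beh += age_c[:, None] * cfg.confound_strength_age * beh_age_load[None, :] * 10.0
    beh += fd_c[:, None] * cfg.confound_strength_fd * beh_fd_load[None, :] * 10.0

    mask = np.ones(cfg.grid_shape, dtype=bool)
    subject_ids = [f"sub-{i:04d}" for i in range(n)]
    sd_matrix = SDMatrix(
        matrix=sd,
        voxel_index=np.argwhere(mask),
        subject_ids=subject_ids,
        mask=mask,
        affine=np.eye(4),
    )
    names = measure_names or [f"measure_{b:02d}" for b in range(p)]
    frame = pd.DataFrame({"subject_id": subject_ids, "age": age, "mean_fd": mean_fd})
    frame[names] = beh
    table = BehaviorTable(frame=frame, measure_names=list(names))

    truth = SyntheticTruth(
        latent_scores=latent,
        voxel_saliences_true=u,
        behavior_weights_true=w,
        confound_coeffs={
            "age_brain": cfg.confound_strength_age * voxel_age_load,
            "fd_brain": cfg.confound_strength_fd * voxel_fd_load,
            "age_behavior": cfg.confound_strength_age * beh_age_load * 10.0,
            "fd_behavior": cfg.confound_strength_fd * beh_fd_load * 10.0,
        },
        target_sd_map=sd,
        age=age,
        mean_fd=mean_fd,
    )
    return sd_matrix, table, truth


def _ar1_series(
    rng: np.random.Generator, phi: float, n_timepoints: int, n_series: int
) -> np.ndarray:
    """Stationary AR(1) innovations, one series per row."""
    eps = rng.standard_normal((n_series, n_timepoints))
    x = np.empty_like(eps)
    # stationary start so early samples are not systematically smaller
    x[:, 0] = eps[:, 0] / np.sqrt(1.0 - phi**2)
    for t in range(1, n_timepoints):
        x[:, t] = phi * x[:, t - 1] + eps[:, t]
    return x


def generate_timeseries(
    config: GeneratorConfig,
    truth: SyntheticTruth,
    mean_offset: float = 100.0,
) -> list[SubjectScan]:
    """Emit per-subject 4D AR(1) time series realizing ``truth.target_sd_map``.

    Each voxel's series is rescaled after simulation so its sample SD
    (n-1 denominator) equals the target exactly; a voxel with target SD 0
    gets a constant series.  The mean offset is arbitrary and positive so
    grand-mean normalization is well defined.
    """
    if config.n_timepoints < 3:
        raise ValueError("n_timepoints must be >= 3")
    if truth.target_sd_map is None:
        raise ValueError("truth has no target_sd_map")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mask = np.ones(config.grid_shape, dtype=bool)
    scans: list[SubjectScan] = []
    for i in range(truth.target_sd_map.shape[0]):
        target = truth.target_sd_map[i]
        x = _ar1_series(rng, config.ar_coefficient, config.n_timepoints, target.size)
        sample_sd = x.std(axis=1, ddof=1)
        sample_sd[sample_sd == 0] = 1.0
        x = (x - x.mean(axis=1, keepdims=True)) / sample_sd[:, None]
        x *= target[:, None]
        x += mean_offset
        data = x.reshape(*config.grid_shape, config.n_timepoints)
        scans.append(
            SubjectScan(data=data, mask=mask, affine=np.eye(4), subject_id=f"sub-{i:04d}")
        )
    return scans
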