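"""Behavioral partial least squares (PLS) with resampling inference.

Behavioral PLS relates a subjects x voxels brain block to a subjects x
measures behavior block through the singular value decomposition of their
cross-block association matrix R (measures x voxels).  Each latent
variable (LV) is a pair of singular vectors — per-measure "behavior
saliences" and per-voxel "voxel saliences" — with a singular value whose
square, normalized by the sum of all squared singular values, is the
fraction of cross-block covariance the LV explains.

Inference is nonparametric:

* permutation test — behavior rows are permuted relative to brain rows,
  the k-th permuted singular value is compared to the k-th observed, and
  p_k = (#exceedances + 1) / (n_permutations + 1);
* bootstrap — subjects are resampled with replacement, the full pipeline
  (column standardization, cross-block matrix, SVD) is recomputed, and the
  stability of each voxel salience is summarized by the bootstrap ratio
  (BSR): original salience / bootstrap standard error.  Brain-score /
  behavior correlations get percentile confidence intervals from the same
  resamples.

By default R is the Pearson correlation matrix (both blocks column
standardized), the convention of the standard behavioral-PLS toolbox; a
raw covariance mode (centering only) is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .variability import DataError

Mode = Literal["correlation", "covariance"]


def _column_check(block: np.ndarray, name: str) -> None:
    if not np.isfinite(block).all():
        raise DataError(f"non-finite values in {name} block")
    sd = block.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DataError(f"zero-variance column(s) in {name} block: {zero[:5].tolist()}")


def _standardize(block: np.ndarray, mode: Mode) -> np.ndarray:
    centered = block - block.mean(axis=0)
    if mode == "correlation":
        return centered / block.std(axis=0, ddof=1)
    return centered


def cross_block_matrix(
    brain: np.ndarray, behavior: np.ndarray, mode: Mode = "correlation"
) -> np.ndarray:
    """Measures x voxels association matrix across subjects.

    In ``correlation`` mode entry (b, v) is the Pearson correlation between
    measure b and voxel v; in ``covariance`` mode the sample covariance.
    Rows of the two blocks must be the same subjects in the same order.
    """
    brain = np.asarray(brain, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if brain.shape[0] != behavior.shape[0]:
        raise DataError("brain and behavior blocks disagree on subject count")
    n = brain.shape[0]
    if n < 3:
        raise DataError("need at least 3 subjects")
    _column_check(brain, "brain")
    _column_check(behavior, "behavior")
    yb = _standardize(behavior, mode)
    yv = _standardize(brain, mode)
    return (yb.T @ yv) / (n - 1)


@dataclass
class PLSDecomposition:
    behavior_saliences: np.ndarray  # measures x LVs
    voxel_saliences: np.ndarray  # voxels x LVs
    singular_values: np.ndarray  # LVs, nonincreasing
    covariance_explained: np.ndarray  # LVs, sums to 1
    brain_scores: np.ndarray | None = None  # subjects x LVs

    @property
    def n_lv(self) -> int:
        return self.singular_values.size


def decompose(
    R: np.ndarray,
    brain: np.ndarray | None = None,
    mode: Mode = "correlation",
) -> PLSDecomposition:
    """SVD of the cross-block matrix into latent variables.

    R = U S V^T with U the behavior saliences and V the voxel saliences.
    A deterministic sign convention is applied per LV: the behavior
    salience of largest magnitude is made positive.  When the brain block
    is supplied, per-subject brain scores are its (standardized) rows
    projected onto the voxel saliences.
    """
    R = np.asarray(R, dtype=float)
    if not np.isfinite(R).all():
        raise DataError("non-finite entries in cross-block matrix")
    u, s, vt = np.linalg.svd(R, full_matrices=False)
    v = vt.T
    # sign convention: dominant behavior salience positive within each LV
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    u = u * flip
    v = v * flip
    total = np.sum(s**2)
    cov_explained = s**2 / total if total > 0 else np.zeros_like(s)
    scores = None
    if brain is not None:
        scores = _standardize(np.asarray(brain, dtype=float), mode) @ v
    return PLSDecomposition(
        behavior_saliences=u,
        voxel_saliences=v,
        singular_values=s,
        covariance_explained=cov_explained,
        brain_scores=scores,
    )


@dataclass
class PermutationResult:
    n_permutations: int
    p_values: np.ndarray  # per LV, in (0, 1]
    permuted_singular_values: np.ndarray  # permutations x LVs
    seed: int | None = None


def permutation_test(
    brain: np.ndarray,
    behavior: np.ndarray,
    n_permutations: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    mode: Mode = "correlation",
) -> PermutationResult:
    """Permutation test of the singular values.

    For each resample, behavior rows are permuted relative to brain rows
    and the cross-block matrix and its singular values recomputed.  The
    k-th permuted value is compared with the k-th observed (no rotation),
    and p_k = (#{s_perm_k >= s_obs_k} + 1) / (n_permutations + 1), which
    bottoms out at 1/(N+1) rather than zero.
    """
    if n_permutations < 1:
        raise DataError("n_permutations must be >= 1")
    brain = np.asarray(brain, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    s_obs = np.linalg.svd(
        cross_block_matrix(brain, behavior, mode), compute_uv=False
    )
    rng = np.random.default_rng(seed)
    n = brain.shape[0]
    perm_s = np.empty((n_permutations, s_obs.size))
    for j in range(n_permutations):
        order = rng.permutation(n)
        perm_s[j] = np.linalg.svd(
            cross_block_matrix(brain, behavior[order], mode), compute_uv=False
        )
    exceed = (perm_s >= s_obs[None, :]).sum(axis=0)
    p = (exceed + 1) / (n_permutations + 1)
    return PermutationResult(
        n_permutations=n_permutations,
        p_values=p,
        permuted_singular_values=perm_s,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass
class BootstrapResult:
    n_bootstrap: int
    bsr: np.ndarray  # voxels x LVs; +/-inf flags zero-SE (perfectly stable) voxels
    salience_se: np.ndarray  # voxels x LVs
    stable_mask: np.ndarray  # voxels x LVs bool: SE == 0 with nonzero salience
    behavior_correlations: np.ndarray  # measures x LVs
    correlation_ci_low: np.ndarray  # measures x LVs
    correlation_ci_high: np.ndarray  # measures x LVs
    n_redrawn: int = 0
    seed: int | None = None


def _align_sign(v_boot: np.ndarray, v_ref: np.ndarray) -> np.ndarray:
    """Resolve per-LV reflection ambiguity by the sign of <v_boot, v_ref>."""
    dots = np.einsum("vk,vk->k", v_boot, v_ref)
    flip = np.where(dots < 0, -1.0, 1.0)
    return v_boot * flip


def _procrustes_align(
    u_boot: np.ndarray, v_boot: np.ndarray, u_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal Procrustes rotation of a bootstrap solution onto the original."""
    a, _, bt = np.linalg.svd(u_ref.T @ u_boot, full_matrices=False)
    rot = (a @ bt).T
    return u_boot @ rot, v_boot @ rot


def _pearson_columns(scores: np.ndarray, behavior: np.ndarray) -> np.ndarray:
    """Correlation of each behavior column with each score column -> measures x LVs."""
    zs = _standardize(scores, "correlation")
    zb = _standardize(behavior, "correlation")
    return (zb.T @ zs) / (scores.shape[0] - 1)


def bootstrap_inference(
    brain: np.ndarray,
    behavior: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    ci_level: float = 0.95,
    mode: Mode = "correlation",
    align: Literal["sign", "procrustes"] = "sign",
    max_redraws: int = 1000,
) -> BootstrapResult:
    """Bootstrap stability of voxel saliences and of brain-score correlations.

    Subjects are resampled with replacement; per resample the full pipeline
    (standardization, cross-block matrix, SVD) is recomputed and the
    resampled saliences are aligned to the original — by sign of the dot
    product per LV (default) or by full orthogonal Procrustes rotation.
    The per-voxel bootstrap SE uses the n-1 denominator across resamples.
    Voxels whose saliences do not vary at all across resamples (SE = 0)
    are flagged in ``stable_mask`` and given a signed infinite BSR rather
    than overflowing.  Resamples that produce a zero-variance column are
    redrawn (counted in ``n_redrawn``).
    """
    if n_bootstrap < 2:
        raise DataError("n_bootstrap must be >= 2")
    brain = np.asarray(brain, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    n = brain.shape[0]
    base = decompose(cross_block_matrix(brain, behavior, mode), brain=brain, mode=mode)
    corr_obs = _pearson_columns(base.brain_scores, behavior)

    rng = np.random.default_rng(seed)
    v_samples = np.empty((n_bootstrap, *base.voxel_saliences.shape))
    corr_samples = np.empty((n_bootstrap, *corr_obs.shape))
    n_redrawn = 0
    j = 0
    while j < n_bootstrap:
        idx = rng.integers(0, n, size=n)
        b_brain, b_beh = brain[idx], behavior[idx]
        if (b_brain.std(axis=0) == 0).any() or (b_beh.std(axis=0) == 0).any():
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise DataError("too many degenerate bootstrap resamples")
            continue
        dec = decompose(cross_block_matrix(b_brain, b_beh, mode), mode=mode)
        if align == "procrustes":
            u_al, v_al = _procrustes_align(
                dec.behavior_saliences, dec.voxel_saliences, base.behavior_saliences
            )
        else:
            v_al = _align_sign(dec.voxel_saliences, base.voxel_saliences)
        v_samples[j] = v_al
        scores = _standardize(b_brain, mode) @ v_al
        corr_samples[j] = _pearson_columns(scores, b_beh)
        j += 1

    se = v_samples.std(axis=0, ddof=1)
    sal = base.voxel_saliences
    stable = (se == 0) & (sal != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, sal / np.where(se > 0, se, 1.0), 0.0)
    bsr[stable] = np.sign(sal[stable]) * np.inf

    alpha = (1.0 - ci_level) / 2.0
    ci_low = np.quantile(corr_samples, alpha, axis=0)
    ci_high = np.quantile(corr_samples, 1.0 - alpha, axis=0)
    return BootstrapResult(
        n_bootstrap=n_bootstrap,
        bsr=bsr,
        salience_se=se,
        stable_mask=stable,
        behavior_correlations=corr_obs,
        correlation_ci_low=ci_low,
        correlation_ci_high=ci_high,
        n_redrawn=n_redrawn,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass
class PLSResult:
    """Bundle of decomposition + resampling inference + provenance."""

    decomposition: PLSDecomposition
    permutation: PermutationResult
    bootstrap: BootstrapResult
    measure_names: list[str] = field(default_factory=list)
    mode: Mode = "correlation"
    seed: int | None = None


def run_behavioral_pls(
    brain: np.ndarray,
    behavior: np.ndarray,
    n_permutations: int = 1000,
    n_bootstrap: int = 1000,
    seed: int | None = 0,
    mode: Mode = "correlation",
    measure_names: list[str] | None = None,
    align: Literal["sign", "procrustes"] = "sign",
) -> PLSResult:
    """End-to-end behavioral PLS: decomposition, permutation, bootstrap.

    All randomness flows from ``seed`` through a two-way split
    (permutation stream, bootstrap stream), so a repeated run with the
    same inputs and seed is bit-identical.
    """
    ss = np.random.SeedSequence(seed)
    perm_ss, boot_ss = ss.spawn(2)
    R = cross_block_matrix(brain, behavior, mode)
    dec = decompose(R, brain=brain, mode=mode)
    perm = permutation_test(brain, behavior, n_permutations, perm_ss, mode)
    perm.seed = seed
    boot = bootstrap_inference(
        brain, behavior, n_bootstrap, boot_ss, mode=mode, align=align
    )
    boot.seed = seed
    return PLSResult(
        decomposition=dec,
        permutation=perm,
        bootstrap=boot,
        measure_names=list(measure_names or []),
        mode=mode,
        seed=seed,
    )
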