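"""Nuisance-variable residualization for the brain and behavior blocks.

Age is a strong correlate of both voxelwise BOLD variability and most of
the behavioral measures, and residual head motion (summarized as mean
framewise displacement, FD) contaminates the variability maps.  Before the
brain-behavior decomposition, age and mean FD are regressed out of the
subjects x voxels variability matrix and age out of the behavioral scores.
Confounds are entered jointly in a single ordinary-least-squares fit per
column (intercept + all confounds), which is order-invariant and spans the
same space as sequential regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import BehaviorTable
from .variability import DataError, SDMatrix


@dataclass
class ConfoundSpec:
    """Which confound columns to remove from each block."""

    brain_confounds: list[str] = field(default_factory=lambda: ["age", "mean_fd"])
    behavior_confounds: list[str] = field(default_factory=lambda: ["age"])


def residualize_columns(
    matrix: np.ndarray,
    confounds: np.ndarray,
    confound_names: list[str] | None = None,
) -> np.ndarray:
    """Replace each column by its OLS residual on an intercept + confounds.

    Parameters
    ----------
    matrix : (n_subjects, n_variables)
    confounds : (n_subjects, n_confounds)

    Residual columns have mean zero and are orthogonal to every confound;
    the operation is a projection and hence idempotent.
    """
    matrix = np.asarray(matrix, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    n, k = confounds.shape
    if matrix.shape[0] != n:
        raise DataError("matrix and confounds disagree on subject count")
    if n < k + 2:
        raise DataError(f"need at least {k + 2} subjects for {k} confound(s)")
    if not np.isfinite(matrix).all() or not np.isfinite(confounds).all():
        raise DataError("missing or non-finite values are not allowed")
    names = confound_names or [f"confound_{i}" for i in range(k)]
    # a confound indistinguishable from the intercept makes the design singular
    for j in range(k):
        if np.ptp(confounds[:, j]) == 0:
            raise DataError(f"confound {names[j]!r} is constant (rank-deficient design)")
    design = np.column_stack([np.ones(n), confounds])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DataError(f"rank-deficient confound design: {names}")
    beta, *_ = np.linalg.lstsq(design, matrix, rcond=None)
    return matrix - design @ beta


def prepare_blocks(
    sd: SDMatrix,
    behavior: BehaviorTable,
    spec: ConfoundSpec | None = None,
    adjust: bool = True,
) -> tuple[SDMatrix, BehaviorTable]:
    """Residualize both blocks for PLS, preserving subject order.

    With ``adjust=True`` the brain block loses all ``spec.brain_confounds``
    and every behavioral measure loses ``spec.behavior_confounds``.  With
    ``adjust=False`` only mean FD is removed from the brain block and the
    behavioral scores are passed through untouched — the preprocessing used
    for the age-unadjusted younger-subsample analysis.
    """
    spec = spec or ConfoundSpec()
    ids_brain = list(sd.subject_ids)
    ids_beh = list(behavior.frame["subject_id"].astype(str))
    if ids_brain != ids_beh:
        raise DataError("subject_id order mismatch between brain and behavior blocks")

    if adjust:
        brain_names = list(spec.brain_confounds)
        beh_names = list(spec.behavior_confounds)
    else:
        brain_names = ["mean_fd"]
        beh_names = []

    brain_conf = behavior.confound_matrix(brain_names)
    sd_out = SDMatrix(
        matrix=residualize_columns(sd.matrix, brain_conf, brain_names),
        voxel_index=sd.voxel_index,
        subject_ids=sd.subject_ids,
        mask=sd.mask,
        affine=sd.affine,
    )

    frame = behavior.frame.copy()
    if beh_names:
        beh_conf = behavior.confound_matrix(beh_names)
        measures = frame[behavior.measure_names].to_numpy(dtype=float)
        frame[behavior.measure_names] = residualize_columns(
            measures, beh_conf, beh_names
        )
    beh_out = BehaviorTable(frame=frame, measure_names=list(behavior.measure_names))
    return sd_out, beh_out
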