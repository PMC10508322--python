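"""Per-voxel temporal variability maps from 4D resting-state BOLD data.

The variability measure is the temporal standard deviation of each voxel's
time series (BOLD-SD), computed after the whole scan has been rescaled so
that the grand mean over all in-brain voxels and timepoints is 100.  The
mean square successive difference (MSSD, the classical von Neumann
statistic) is available as an alternative metric; on realistic data the two
are very highly correlated across voxels.

Subject-level maps are stacked into a subjects x voxels matrix over a
common mask; that matrix is the brain block entering the behavioral PLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class DataError(ValueError):
    """Raised when input data violate a contract (shape, mask, range)."""


@dataclass
class SubjectScan:
    """One subject's denoised 4D resting time series plus brain mask.

    ``data`` is (x, y, z, t) in BOLD units, ``mask`` a 3D boolean array on
    the same spatial grid, ``affine`` the voxel-to-mm mapping.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_id: str = "sub-unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise DataError(f"scan data must be 4D, got ndim={self.data.ndim}")
        if self.mask.shape != self.data.shape[:3]:
            raise DataError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.data.shape[:3]}"
            )
        if not self.mask.any():
            raise DataError("mask is empty")
        if self.data.shape[3] < 3:
            raise DataError(
                f"need at least 3 timepoints, got {self.data.shape[3]}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class SDMap:
    """A 3D per-voxel variability map; values are defined inside the mask only."""

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_id: str = "sub-unknown"
    metric_name: str = "sd"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise DataError("values and mask shapes differ")

    def in_mask(self) -> np.ndarray:
        """Masked values in C-order linearization."""
        return self.values[self.mask]


@dataclass
class SDMatrix:
    """Subjects x in-mask-voxels variability matrix with voxel bookkeeping.

    Columns follow the C-order linearization of ``mask``; ``voxel_index``
    maps each column to its (i, j, k) voxel indices.
    """

    matrix: np.ndarray
    voxel_index: np.ndarray  # n_voxels x 3 integer indices
    subject_ids: list[str]
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DataError("SDMatrix.matrix must be 2D (subjects x voxels)")
        if self.matrix.shape[0] != len(self.subject_ids):
            raise DataError("row count does not match subject_ids")
        if self.matrix.shape[1] != self.voxel_index.shape[0]:
            raise DataError("column count does not match voxel_index")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    def voxel_mm(self) -> np.ndarray:
        """mm coordinates of each voxel column via the affine."""
        ijk1 = np.hstack([self.voxel_index, np.ones((self.n_voxels, 1))])
        return (self.affine @ ijk1.T).T[:, :3]

    def unstack(self, row: int, metric_name: str = "sd") -> SDMap:
        """Rebuild subject ``row``'s 3D map from its matrix row."""
        vol = np.zeros(self.mask.shape, dtype=float)
        vol[self.mask] = self.matrix[row]
        return SDMap(
            values=vol,
            mask=self.mask,
            affine=self.affine,
            subject_id=self.subject_ids[row],
            metric_name=metric_name,
        )

    def with_rows(self, keep: np.ndarray) -> "SDMatrix":
        """Row subset (subject selection), preserving voxel bookkeeping."""
        keep = np.asarray(keep)
        return SDMatrix(
            matrix=self.matrix[keep],
            voxel_index=self.voxel_index,
            subject_ids=[self.subject_ids[i] for i in np.atleast_1d(keep)],
            mask=self.mask,
            affine=self.affine,
        )


def normalize_grand_mean(scan: SubjectScan, target: float = 100.0) -> SubjectScan:
    """Rescale so the mean over all in-mask voxels and timepoints equals ``target``.

    Only in-mask voxels are rescaled; background voxels are left untouched.
    The operation is invariant to any positive rescaling of the input.
    """
    grand_mean = scan.data[scan.mask].mean()
    if not np.isfinite(grand_mean) or grand_mean <= 0:
        raise DataError(
            f"in-mask grand mean must be positive, got {grand_mean!r}"
        )
    out = scan.data.copy()
    out[scan.mask] *= target / grand_mean
    return SubjectScan(out, scan.mask, scan.affine, scan.subject_id)


def compute_sd_map(scan: SubjectScan, ddof: int = 1) -> SDMap:
    """Per-voxel temporal standard deviation (BOLD-SD).

    Each in-mask voxel's mean is subtracted and the standard deviation of
    the series is taken, with the sample (n-1) denominator by default
    (``ddof`` is exposed because the convention changes the absolute scale).
    """
    if scan.n_timepoints < 3:
        raise DataError("need at least 3 timepoints for an SD map")
    values = np.zeros(scan.mask.shape, dtype=float)
    values[scan.mask] = scan.data[scan.mask].std(axis=1, ddof=ddof)
    return SDMap(values, scan.mask, scan.affine, scan.subject_id, "sd")


def compute_mssd_map(scan: SubjectScan) -> SDMap:
    """Per-voxel mean square successive difference (von Neumann statistic).

    MSSD = mean over t of (x[t+1] - x[t])^2; no division by two and no
    square root.  Like the SD it is invariant to adding a constant to a
    voxel's series; for white noise E[MSSD] = 2 Var.
    """
    if scan.n_timepoints < 3:
        raise DataError("need at least 3 timepoints for an MSSD map")
    series = scan.data[scan.mask]
    mssd = np.mean(np.diff(series, axis=1) ** 2, axis=1)
    values = np.zeros(scan.mask.shape, dtype=float)
    values[scan.mask] = mssd
    return SDMap(values, scan.mask, scan.affine, scan.subject_id, "mssd")


def stack_sd_maps(
    maps: Iterable[SDMap],
    common_mask: np.ndarray | None = None,
) -> SDMatrix:
    """Stack per-subject maps into a subjects x voxels matrix.

    All maps must share grid shape and affine.  The analysis mask defaults
    to the intersection of the subject masks; a supplied ``common_mask``
    must be contained in every subject mask.  Columns are ordered by the
    C-order linearization of the mask, recorded in ``voxel_index``.
    """
    maps = list(maps)
    if not maps:
        raise DataError("no maps to stack")
    ref = maps[0]
    for m in maps[1:]:
        if m.values.shape != ref.values.shape:
            raise DataError(
                f"grid shape mismatch: {m.subject_id} has {m.values.shape}, "
                f"expected {ref.values.shape}"
            )
        if not np.allclose(m.affine, ref.affine):
            raise DataError(f"affine mismatch for {m.subject_id}")
    if common_mask is None:
        common_mask = np.logical_and.reduce([m.mask for m in maps])
    else:
        common_mask = np.asarray(common_mask, dtype=bool)
        if common_mask.shape != ref.values.shape:
            raise DataError("common_mask shape mismatch")
        for m in maps:
            if np.any(common_mask & ~m.mask):
                raise DataError(
                    f"common_mask extends outside {m.subject_id}'s mask"
                )
    if not common_mask.any():
        raise DataError("common mask is empty")
    voxel_index = np.argwhere(common_mask)  # C-order, matches boolean indexing
    matrix = np.stack([m.values[common_mask] for m in maps])
    return SDMatrix(
        matrix=matrix,
        voxel_index=voxel_index,
        subject_ids=[m.subject_id for m in maps],
        mask=common_mask,
        affine=ref.affine,
    )


def sd_map_from_scan(
    scan: SubjectScan,
    metric: str = "sd",
    normalize: bool = True,
    ddof: int = 1,
) -> SDMap:
    """Convenience wrapper: optional grand-mean normalization then SD or MSSD."""
    if normalize:
        scan = normalize_grand_mean(scan)
    if metric == "sd":
        return compute_sd_map(scan, ddof=ddof)
    if metric == "mssd":
        return compute_mssd_map(scan)
    raise ValueError(f"unknown metric {metric!r} (expected 'sd' or 'mssd')")
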