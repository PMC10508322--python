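"""NIfTI and tabular I/O helpers.

NIfTI-1 is the interchange format for scans, masks, SD maps, BSR maps and
atlases; the subjects x voxels SD matrix is cached as a compressed ``.npz``
container with its voxel bookkeeping inside.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .variability import DataError, SDMap, SDMatrix, SubjectScan


def load_scan(
    scan_path: str | Path,
    mask_path: str | Path | None = None,
    subject_id: str | None = None,
) -> SubjectScan:
    """Load a 4D NIfTI scan (and optional 3D mask; defaults to nonzero voxels)."""
    img = nib.load(str(scan_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DataError(f"{scan_path}: expected 4D data, got shape {data.shape}")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.any(data != 0, axis=3)
    sid = subject_id or Path(scan_path).name.split(".")[0]
    return SubjectScan(data=data, mask=mask, affine=img.affine, subject_id=sid)


def save_map(sd_map: SDMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(sd_map.values.astype(np.float32), sd_map.affine), str(path))


def load_map(
    path: str | Path,
    mask_path: str | Path | None = None,
    subject_id: str | None = None,
    metric_name: str = "sd",
) -> SDMap:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if values.ndim != 3:
        raise DataError(f"{path}: expected a 3D map, got shape {values.shape}")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = values != 0
    sid = subject_id or Path(path).name.split(".")[0]
    return SDMap(values=values, mask=mask, affine=img.affine,
                 subject_id=sid, metric_name=metric_name)


def save_volume(values: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def save_sd_matrix(sd: SDMatrix, path: str | Path) -> None:
    np.savez_compressed(
        path,
        matrix=sd.matrix,
        voxel_index=sd.voxel_index,
        subject_ids=np.array(sd.subject_ids),
        mask=sd.mask,
        affine=sd.affine,
    )


def load_sd_matrix(path: str | Path) -> SDMatrix:
    with np.load(path, allow_pickle=False) as z:
        return SDMatrix(
            matrix=z["matrix"],
            voxel_index=z["voxel_index"],
            subject_ids=[str(s) for s in z["subject_ids"]],
            mask=z["mask"].astype(bool),
            affine=z["affine"],
        )
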