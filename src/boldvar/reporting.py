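"""Thresholding, cluster extraction and network-contribution summaries.

Bootstrap-ratio (BSR) maps are thresholded at |BSR| >= cutoff (default
2.5), supra-threshold voxels are grouped into connected components
separately for positive and negative signs, components smaller than the
cluster minimum (default 15 voxels) are discarded, and each surviving
cluster is reported with its size, peak voxel and peak BSR.  Overlaying
the resulting significance mask on a parcellation (seven functional
networks plus anatomically defined cerebellum / medial-temporal /
subcortical groups) yields, per network, the proportion of its voxels
that are significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .pls import PLSResult
from .variability import DataError


@dataclass
class ThresholdSpec:
    """BSR cutoff, cluster-extent minimum and voxel connectivity (6/18/26)."""

    bsr_cutoff: float = 2.5
    min_cluster_voxels: int = 15
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.bsr_cutoff <= 0:
            raise ValueError("bsr_cutoff must be positive")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


CLUSTER_COLUMNS = [
    "cluster_id", "sign", "size", "peak_i", "peak_j", "peak_k",
    "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_bsr",
]


def threshold_and_cluster(
    bsr_map: np.ndarray,
    spec: ThresholdSpec | None = None,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold a 3D BSR map and extract signed clusters.

    Positive and negative supra-threshold voxels are labeled separately
    (opposite signs never merge), components below the extent minimum are
    dropped, and the cluster table is sorted by peak |BSR| descending.
    Returns the binary significance mask and the table.
    """
    spec = spec or ThresholdSpec()
    bsr = np.asarray(bsr_map, dtype=float)
    if bsr.ndim != 3:
        raise DataError("bsr_map must be 3D")
    if mask is not None:
        bsr = np.where(np.asarray(mask, dtype=bool), bsr, 0.0)
    if not np.isfinite(bsr).all():
        # +/-inf marks perfectly stable voxels; they are always supra-threshold
        bsr = np.nan_to_num(bsr, nan=0.0, posinf=np.finfo(float).max,
                            neginf=-np.finfo(float).max)
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)

    sig = np.zeros(bsr.shape, dtype=bool)
    rows: list[dict] = []
    cluster_id = 0
    for sign, supra in (
        (+1, bsr >= spec.bsr_cutoff),
        (-1, bsr <= -spec.bsr_cutoff),
    ):
        labels, n_comp = ndimage.label(supra, structure=spec.structure)
        for comp in range(1, n_comp + 1):
            voxels = np.argwhere(labels == comp)
            if voxels.shape[0] < spec.min_cluster_voxels:
                continue
            comp_vals = bsr[labels == comp]
            peak_local = np.argmax(sign * comp_vals)
            peak_ijk = voxels[peak_local]
            peak_mm = affine @ np.append(peak_ijk, 1.0)
            sig[labels == comp] = True
            cluster_id += 1
            rows.append(
                {
                    "cluster_id": cluster_id,
                    "sign": "+" if sign > 0 else "-",
                    "size": int(voxels.shape[0]),
                    "peak_i": int(peak_ijk[0]),
                    "peak_j": int(peak_ijk[1]),
                    "peak_k": int(peak_ijk[2]),
                    "peak_x_mm": float(peak_mm[0]),
                    "peak_y_mm": float(peak_mm[1]),
                    "peak_z_mm": float(peak_mm[2]),
                    "peak_bsr": float(comp_vals[peak_local]),
                }
            )
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    if len(table):
        table = (
            table.reindex(table["peak_bsr"].abs().sort_values(ascending=False).index)
            .reset_index(drop=True)
        )
        table["cluster_id"] = np.arange(1, len(table) + 1)
    return sig, table


@dataclass
class AtlasDefinition:
    """Integer parcel volume plus a parcel -> network/region-group mapping.

    ``labels`` must have columns ``label`` (the integer in the volume) and
    ``network`` (the group name); an optional ``parcel_name`` column gives
    anatomical labels.  Parcels present in the volume but absent from the
    table are left unassigned (reported separately by validation).
    """

    volume: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        if self.volume.ndim != 3:
            raise DataError("atlas volume must be 3D")
        for col in ("label", "network"):
            if col not in self.labels.columns:
                raise DataError(f"atlas label table missing column {col!r}")
        if self.labels["label"].duplicated().any():
            raise DataError("duplicate parcel labels in atlas table")

    def unmapped_labels(self) -> list[int]:
        present = set(np.unique(self.volume)) - {0}
        mapped = set(self.labels["label"].astype(int))
        return sorted(present - mapped)

    @classmethod
    def from_files(cls, volume_path: str | Path, labels_path: str | Path) -> "AtlasDefinition":
        import nibabel as nib

        img = nib.load(str(volume_path))
        vol = np.asarray(img.dataobj).astype(int)
        labels = pd.read_csv(labels_path, sep="\t")
        return cls(volume=vol, labels=labels)


def network_contributions(
    sig_mask: np.ndarray, atlas: AtlasDefinition
) -> pd.DataFrame:
    """Per-network significant-voxel counts and proportions.

    Returns a table with ``network``, ``n_significant_voxels``,
    ``n_total_voxels`` and ``proportion`` (= significant / total).  Voxels
    outside the atlas (label 0 or unmapped) are not assigned to any
    network, so the significant counts may sum to less than the mask total.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    if sig_mask.shape != atlas.volume.shape:
        raise DataError(
            f"grid mismatch: mask {sig_mask.shape} vs atlas {atlas.volume.shape}"
        )
    rows = []
    for network, group in atlas.labels.groupby("network", sort=True):
        labels = group["label"].astype(int).to_numpy()
        in_net = np.isin(atlas.volume, labels)
        total = int(in_net.sum())
        n_sig = int((in_net & sig_mask).sum())
        rows.append(
            {
                "network": network,
                "n_significant_voxels": n_sig,
                "n_total_voxels": total,
                "proportion": n_sig / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def lv_summary_table(result: PLSResult) -> pd.DataFrame:
    dec, perm = result.decomposition, result.permutation
    return pd.DataFrame(
        {
            "lv": np.arange(1, dec.n_lv + 1),
            "singular_value": dec.singular_values,
            "covariance_explained": dec.covariance_explained,
            "p_value": perm.p_values,
        }
    )


def behavior_correlation_table(result: PLSResult, lv: int = 0) -> pd.DataFrame:
    """Behavior correlations with the LV's brain scores + bootstrap CIs.

    A measure is flagged ``robust`` when its confidence interval excludes
    zero.
    """
    boot = result.bootstrap
    names = result.measure_names or [
        f"measure_{b:02d}" for b in range(boot.behavior_correlations.shape[0])
    ]
    lo = boot.correlation_ci_low[:, lv]
    hi = boot.correlation_ci_high[:, lv]
    table = pd.DataFrame(
        {
            "measure": names,
            "correlation": boot.behavior_correlations[:, lv],
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    table["robust"] = (lo > 0) | (hi < 0)
    return table


def lv_report(
    result: PLSResult,
    threshold: ThresholdSpec | None = None,
    atlas: AtlasDefinition | None = None,
    lv: int = 0,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    voxel_index: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Assemble (and optionally write) the full report bundle for one LV.

    Contents: LV summary (singular values, covariance explained,
    permutation p), behavior correlations with CIs and robustness flags,
    the thresholded cluster table, and — when an atlas is supplied — the
    per-network contribution table.
    """
    threshold = threshold or ThresholdSpec()
    bundle: dict = {
        "lv_summary": lv_summary_table(result),
        "behavior_correlations": behavior_correlation_table(result, lv),
    }
    if voxel_index is not None and grid_shape is not None:
        bsr_vol = np.zeros(grid_shape, dtype=float)
        idx = np.asarray(voxel_index)
        bsr_vol[idx[:, 0], idx[:, 1], idx[:, 2]] = result.bootstrap.bsr[:, lv]
        sig, clusters = threshold_and_cluster(bsr_vol, threshold, affine, mask)
        bundle["bsr_volume"] = bsr_vol
        bundle["significance_mask"] = sig
        bundle["clusters"] = clusters
        if atlas is not None:
            bundle["network_contributions"] = network_contributions(sig, atlas)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["lv_summary"].to_csv(out / "lv_summary.tsv", sep="\t", index=False)
        bundle["behavior_correlations"].to_csv(
            out / "behavior_correlations.tsv", sep="\t", index=False
        )
        if "clusters" in bundle:
            bundle["clusters"].to_csv(out / "clusters.tsv", sep="\t", index=False)
        if "network_contributions" in bundle:
            bundle["network_contributions"].to_csv(
                out / "network_contributions.tsv", sep="\t", index=False
            )
    return bundle
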