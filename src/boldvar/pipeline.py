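"""Pipeline driver: configuration, validation, stage orchestration.

Ties the stages together into the two analyses of interest: the
full-sample analysis (age and mean FD regressed out of the variability
maps, age out of the behavioral scores) and the younger-subsample analysis
(subjects below an age threshold, mean FD only removed from the brain
block, behavior unadjusted).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as bio
from .behavior import BehaviorTable, build_behavior_block, classify_meq
from .confounds import ConfoundSpec, prepare_blocks
from .pls import PLSResult, run_behavioral_pls
from .reporting import AtlasDefinition, ThresholdSpec, lv_report
from .variability import DataError, SDMatrix, sd_map_from_scan, stack_sd_maps


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML."""

    # inputs: either 4D scans (scan_paths [+ mask_paths]) or stacked SD matrix
    scan_paths: list[str] = field(default_factory=list)
    mask_paths: list[str] = field(default_factory=list)
    sd_matrix_path: str | None = None
    behavior_path: str | None = None
    atlas_volume_path: str | None = None
    atlas_labels_path: str | None = None
    out_dir: str = "boldvar_out"
    # analysis options
    metric: str = "sd"  # "sd" | "mssd"
    normalize: bool = True
    adjust: bool = True
    subsample_age_below: float | None = None
    measure_order: list[str] | None = None
    brain_confounds: list[str] = field(default_factory=lambda: ["age", "mean_fd"])
    behavior_confounds: list[str] = field(default_factory=lambda: ["age"])
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    seed: int | None = None
    bsr_cutoff: float = 2.5
    min_cluster_voxels: int = 15
    connectivity: int = 26
    pls_mode: str = "correlation"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check paths, subject alignment, value ranges and atlas mapping.

    Fatal problems go to ``errors``; recoverable oddities (e.g. an atlas
    parcel with no network assignment) go to ``warnings``.
    """
    rep = ValidationReport()
    for p in [*config.scan_paths, *config.mask_paths]:
        if not Path(p).exists():
            rep.errors.append(f"missing file: {p}")
    for attr in ("sd_matrix_path", "behavior_path", "atlas_volume_path", "atlas_labels_path"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            rep.errors.append(f"missing file: {p}")
    if not config.scan_paths and config.sd_matrix_path is None:
        rep.errors.append("no brain input: provide scan_paths or sd_matrix_path")
    if config.behavior_path is None:
        rep.errors.append("no behavior table supplied")
    if (config.n_permutations or config.n_bootstrap) and config.seed is None:
        rep.errors.append("seed is mandatory when resampling is requested")
    if rep.errors:
        return rep

    table = BehaviorTable.from_tsv(config.behavior_path)
    if "meq_global" in table.frame.columns:
        meq = table.frame["meq_global"].to_numpy(dtype=float)
        bad = np.flatnonzero((meq < 16) | (meq > 86))
        if bad.size:
            rep.errors.append(
                f"MEQ global score outside [16, 86] for row(s) {bad.tolist()}"
            )
    if "scan_midpoint_time" in table.frame.columns:
        t = table.frame["scan_midpoint_time"].to_numpy(dtype=float)
        if np.any((t < 0) | (t >= 24)):
            rep.errors.append("scan_midpoint_time outside [0, 24)")
    measures = config.measure_order or table.measure_names
    missing_cols = [m for m in measures if m not in table.frame.columns]
    if missing_cols:
        rep.errors.append(f"behavior table missing measure column(s): {missing_cols}")
    else:
        block = table.frame[measures].to_numpy(dtype=float)
        if not np.isfinite(block).all():
            rep.errors.append("missing values in behavioral measures")

    brain_ids: list[str] | None = None
    if config.sd_matrix_path is not None:
        sd = bio.load_sd_matrix(config.sd_matrix_path)
        brain_ids = list(sd.subject_ids)
    if brain_ids is not None:
        beh_ids = table.subject_ids
        only_brain = sorted(set(brain_ids) - set(beh_ids))
        only_beh = sorted(set(beh_ids) - set(brain_ids))
        if only_brain:
            rep.errors.append(f"subjects with scans but no behavior row: {only_brain}")
        if only_beh:
            rep.errors.append(f"subjects with behavior but no scans: {only_beh}")

    if config.atlas_volume_path and config.atlas_labels_path:
        atlas = AtlasDefinition.from_files(
            config.atlas_volume_path, config.atlas_labels_path
        )
        unmapped = atlas.unmapped_labels()
        if unmapped:
            rep.warnings.append(f"atlas parcel label(s) without a network: {unmapped}")
    return rep


def _load_brain(config: PipelineConfig) -> SDMatrix:
    if config.sd_matrix_path is not None:
        return bio.load_sd_matrix(config.sd_matrix_path)
    maps = []
    for i, sp in enumerate(config.scan_paths):
        mp = config.mask_paths[i] if i < len(config.mask_paths) else None
        scan = bio.load_scan(sp, mp)
        maps.append(
            sd_map_from_scan(scan, metric=config.metric, normalize=config.normalize)
        )
    return stack_sd_maps(maps)


def run_pipeline(config: PipelineConfig) -> PLSResult:
    """Execute the full analysis and write artifacts + manifest to out_dir.

    Stage order: variability (if scans given) -> stacking -> subject
    alignment/subsampling -> confound residualization -> behavior block ->
    PLS with permutation and bootstrap -> thresholded report.  Any stage
    error aborts before partial PLS outputs are written.
    """
    report = validate_inputs(config)
    if not report.ok:
        raise DataError("input validation failed: " + "; ".join(report.errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sd = _load_brain(config)
    table = BehaviorTable.from_tsv(config.behavior_path)
    # align behavior rows to brain row order
    order = [table.subject_ids.index(s) for s in sd.subject_ids]
    table = BehaviorTable(
        frame=table.frame.iloc[order].reset_index(drop=True),
        measure_names=table.measure_names,
    )

    n_total = sd.n_subjects
    if config.subsample_age_below is not None:
        keep = np.flatnonzero(
            table.frame["age"].to_numpy(dtype=float) < config.subsample_age_below
        )
        sd = sd.with_rows(keep)
        table = BehaviorTable(
            frame=table.frame.iloc[keep].reset_index(drop=True),
            measure_names=table.measure_names,
        )

    spec = ConfoundSpec(
        brain_confounds=list(config.brain_confounds),
        behavior_confounds=list(config.behavior_confounds),
    )
    sd_res, table_res = prepare_blocks(sd, table, spec, adjust=config.adjust)
    block, measure_order = build_behavior_block(table_res, config.measure_order)

    result = run_behavioral_pls(
        sd_res.matrix,
        block,
        n_permutations=config.n_permutations,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
        mode=config.pls_mode,  # type: ignore[arg-type]
        measure_names=measure_order,
    )

    atlas = None
    if config.atlas_volume_path and config.atlas_labels_path:
        atlas = AtlasDefinition.from_files(
            config.atlas_volume_path, config.atlas_labels_path
        )
    threshold = ThresholdSpec(
        bsr_cutoff=config.bsr_cutoff,
        min_cluster_voxels=config.min_cluster_voxels,
        connectivity=config.connectivity,
    )
    bundle = lv_report(
        result,
        threshold=threshold,
        atlas=atlas,
        mask=sd.mask,
        affine=sd.affine,
        voxel_index=sd.voxel_index,
        grid_shape=sd.mask.shape,
        out_dir=out,
    )
    if "bsr_volume" in bundle:
        bio.save_volume(bundle["bsr_volume"], sd.affine, out / "bsr_lv1.nii.gz")
        bio.save_volume(
            bundle["significance_mask"].astype(np.float32),
            sd.affine,
            out / "significance_mask_lv1.nii.gz",
        )

    input_files = [
        p
        for p in [
            *config.scan_paths,
            *config.mask_paths,
            config.sd_matrix_path,
            config.behavior_path,
            config.atlas_volume_path,
            config.atlas_labels_path,
        ]
        if p
    ]
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "n_subjects_input": n_total,
        "n_subjects_analyzed": sd.n_subjects,
        "n_voxels": sd.n_voxels,
        "measure_order": measure_order,
        "adjust": config.adjust,
        "subsample_age_below": config.subsample_age_below,
        "n_bootstrap_redrawn": result.bootstrap.n_redrawn,
        "input_checksums": {p: _sha256(p) for p in input_files},
        "warnings": report.warnings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def reproduce_published_analysis(
    data_dir: str | Path,
    subsample_age_below: float | None = None,
    seed: int = 0,
    n_permutations: int = 1000,
    n_bootstrap: int = 1000,
) -> PLSResult:
    """Rerun the deposited-data analysis from a local copy of the study deposit.

    Expects ``data_dir`` to hold the deposited per-subject variability maps
    (``sd_matrix.npz`` or per-subject NIfTI maps plus ``mask.nii.gz``) and
    ``behavior.tsv``.  The deposit must be downloaded separately; this
    package ships no subject data.
    """
    data_dir = Path(data_dir)
    if not data_dir.exists():
        raise FileNotFoundError(
            f"deposited-data directory not found: {data_dir}. Download the "
            "study deposit and point data_dir at it."
        )
    cfg = PipelineConfig(
        sd_matrix_path=str(data_dir / "sd_matrix.npz"),
        behavior_path=str(data_dir / "behavior.tsv"),
        out_dir=str(data_dir / "reproduction_out"),
        adjust=subsample_age_below is None,
        subsample_age_below=subsample_age_below,
        n_permutations=n_permutations,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
    return run_pipeline(cfg)
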