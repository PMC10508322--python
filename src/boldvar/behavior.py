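"""Behavioral block assembly: cognitive composites, socioemotional T-scores,
chronotype (MEQ) and the chronotype/test-time synchrony score.

Measure conventions follow the NIH Toolbox: cognitive composites (gF, gC)
are scaled scores with mean 100 / SD 15, the 17 socioemotional scales are
T-scores with mean 50 / SD 10.  The Morningness-Eveningness Questionnaire
(MEQ) global score ranges 16-86, higher meaning a morning chronotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variability import DataError

#: canonical measure panel: 2 cognitive composites, 7 positive and 10
#: negative socioemotional T-scores, MEQ global score and synchrony.
DEFAULT_MEASURES: list[str] = [
    "gF",
    "gC",
    "instrumental_support",
    "emotional_support",
    "friendship",
    "self_efficacy",
    "positive_affect",
    "meaning_purpose",
    "life_satisfaction",
    "perceived_rejection",
    "perceived_hostility",
    "loneliness",
    "fear_somatic_arousal",
    "fear_affect",
    "anger_physical_aggression",
    "anger_hostility",
    "anger_affect",
    "sadness",
    "stress",
    "meq_global",
    "synchrony",
]

#: MEQ five-category bins, inclusive at both ends.
MEQ_BINS: list[tuple[int, int, str]] = [
    (16, 30, "definitely evening"),
    (31, 41, "moderately evening"),
    (42, 58, "neutral"),
    (59, 69, "moderately morning"),
    (70, 86, "definitely morning"),
]

CONFOUND_COLUMNS = ["age", "mean_fd"]


@dataclass
class BehaviorTable:
    """Subjects x measures table with confound columns kept separate.

    ``frame`` holds one row per subject with columns ``subject_id``,
    ``age`` (years), ``mean_fd`` (mm) and the named measures;
    ``measure_names`` lists which columns are analysis measures (the
    confounds never enter the PLS behavior block).
    """

    frame: pd.DataFrame
    measure_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ["subject_id", *CONFOUND_COLUMNS]:
            if col not in self.frame.columns:
                raise DataError(f"behavior table missing required column {col!r}")
        missing = [m for m in self.measure_names if m not in self.frame.columns]
        if missing:
            raise DataError(f"behavior table missing measure column(s): {missing}")

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"].astype(str))

    def confound_matrix(self, names: list[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise DataError(f"unknown confound column(s): {missing}")
        return self.frame[names].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        cols = ["subject_id", *CONFOUND_COLUMNS, *self.measure_names]
        self.frame[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, measure_names: list[str] | None = None) -> "BehaviorTable":
        frame = pd.read_csv(path, sep="\t")
        if measure_names is None:
            measure_names = [
                c
                for c in frame.columns
                if c not in ("subject_id", *CONFOUND_COLUMNS)
            ]
        return cls(frame=frame, measure_names=measure_names)


def classify_meq(meq_global: float) -> str:
    """Map an MEQ global score (16-86) to its five-point chronotype category."""
    if not 16 <= meq_global <= 86:
        raise DataError(f"MEQ global score {meq_global} outside [16, 86]")
    for lo, hi, label in MEQ_BINS:
        if lo <= meq_global <= hi:
            return label
    raise AssertionError("unreachable: MEQ bins cover [16, 86]")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataError("zero variance; z-scores undefined")
    return (x - x.mean()) / sd


def compute_synchrony(
    meq_global: np.ndarray, scan_midpoint_time: np.ndarray
) -> np.ndarray:
    """Synchrony between chronotype and time of testing.

    Scan midpoint clock times t (24-h decimal hours) are reflected to
    24 - t so that larger values mean earlier sessions, matching the MEQ
    direction (higher = morning).  Both vectors are z-scored across the
    sample (n-1 denominator) and the synchrony score is

        s_i = 1 - | z(meq)_i - z(24 - t)_i |

    Bounded above by 1 (perfect chronotype/test-time match), unbounded
    below, and invariant to shifting all scan times by a constant.
    """
    meq = np.asarray(meq_global, dtype=float)
    t = np.asarray(scan_midpoint_time, dtype=float)
    if meq.shape != t.shape or meq.ndim != 1:
        raise DataError("meq and scan time vectors must be 1D and aligned")
    if meq.size < 3:
        raise DataError("need at least 3 subjects to standardize")
    if np.any((t < 0) | (t >= 24)):
        raise DataError("scan_midpoint_time must lie in [0, 24)")
    return 1.0 - np.abs(_zscore(meq) - _zscore(24.0 - t))


def build_behavior_block(
    table: BehaviorTable, measure_order: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Extract the subjects x measures matrix in a fixed column order.

    Returns the matrix and the column order actually used (recorded so
    reports can label saliences and correlations).
    """
    order = list(measure_order) if measure_order is not None else list(table.measure_names)
    missing = [m for m in order if m not in table.frame.columns]
    if missing:
        raise DataError(f"requested measure column(s) not in table: {missing}")
    block = table.frame[order].to_numpy(dtype=float)
    if not np.isfinite(block).all():
        bad = [
            m
            for m in order
            if not np.isfinite(table.frame[m].to_numpy(dtype=float)).all()
        ]
        raise DataError(f"missing values in measure column(s): {bad}")
    return block, order
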