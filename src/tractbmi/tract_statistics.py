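"""Per-tract descriptive statistics and the subjects x measurements matrix.

Each "tract measurement" is one descriptive statistic computed over the FA
values of the voxels forming one atlas tract for one subject.  With the
50-tract parcellation and the default 12-statistic panel this yields 600
measurement columns per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging_io import AtlasVolume, FAVolume, SubjectRecord, extract_tract_voxels

logger = logging.getLogger(__name__)

#: All 13 supported statistic names.
STATISTIC_NAMES: tuple[str, ...] = (
    "arithmetic_mean",
    "median",
    "standard_deviation",
    "range",
    "variance",
    "harmonic_mean",
    "geometric_mean",
    "interquartile_range",
    "maximum",
    "minimum",
    "mean_absolute_deviation",
    "median_absolute_deviation",
    "root_mean_square",
)

#: Default 12-statistic panel (drops mean_absolute_deviation; configurable).
DEFAULT_PANEL: tuple[str, ...] = tuple(
    s for s in STATISTIC_NAMES if s != "mean_absolute_deviation"
)

COLUMN_SEP = "|"


def column_id(tract: str, statistic: str) -> str:
    """Canonical column identifier ``<tract>|<statistic>``."""
    return f"{tract}{COLUMN_SEP}{statistic}"


def split_column_id(column: str) -> tuple[str, str]:
    tract, _, stat = column.rpartition(COLUMN_SEP)
    if not tract or stat not in STATISTIC_NAMES:
        raise ValueError(f"malformed column id {column!r}")
    return tract, stat


def compute_statistic(values: Sequence[float] | np.ndarray, stat: str) -> float:
    """One descriptive statistic of a voxel value list.

    Sample (n-1) denominators are used for variance / standard deviation;
    quartiles use linear interpolation; the harmonic and geometric means are
    computed after dropping non-positive values (FA maps contain exact
    zeros, where both are degenerate).  An empty input — or an input left
    empty by the positivity filter — yields NaN as a missing-value sentinel.
    """
    if stat not in STATISTIC_NAMES:
        raise ValueError(f"unknown statistic {stat!r}")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        logger.warning("empty value list for statistic %s; recording missing value", stat)
        return float("nan")
    if stat == "arithmetic_mean":
        return float(np.mean(x))
    if stat == "median":
        return float(np.median(x))
    if stat == "standard_deviation":
        return float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    if stat == "range":
        return float(np.max(x) - np.min(x))
    if stat == "variance":
        return float(np.var(x, ddof=1)) if x.size > 1 else float("nan")
    if stat in ("harmonic_mean", "geometric_mean"):
        pos = x[x > 0]
        if pos.size == 0:
            logger.warning("no positive values for %s; recording missing value", stat)
            return float("nan")
        return float(sps.hmean(pos)) if stat == "harmonic_mean" else float(sps.gmean(pos))
    if stat == "interquartile_range":
        q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
        return float(q3 - q1)
    if stat == "maximum":
        return float(np.max(x))
    if stat == "minimum":
        return float(np.min(x))
    if stat == "mean_absolute_deviation":
        return float(np.mean(np.abs(x - np.mean(x))))
    if stat == "median_absolute_deviation":
        return float(np.median(np.abs(x - np.median(x))))
    if stat == "root_mean_square":
        return float(np.sqrt(np.mean(x**2)))
    raise AssertionError("unreachable")


@dataclass
class TractMeasurementMatrix:
    """Subjects x (tract, statistic) measurement table with BMI and group.

    ``data`` is indexed by subject id with ``<tract>|<statistic>`` columns;
    ``bmi`` and ``group`` are aligned per-subject series.
    """

    data: pd.DataFrame
    bmi: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate measurement columns: {dupes}")
        self.bmi = self.bmi.reindex(self.data.index)
        self.group = self.group.reindex(self.data.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def rows(self, subject_ids: Iterable[str]) -> "TractMeasurementMatrix":
        ids = list(subject_ids)
        return TractMeasurementMatrix(
            self.data.loc[ids], self.bmi.loc[ids], self.group.loc[ids]
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.group)
        out.insert(0, "bmi", self.bmi)
        out.index.name = "subject_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TractMeasurementMatrix":
        df = pd.read_csv(path, index_col="subject_id")
        df.index = df.index.astype(str)
        for col in ("bmi", "group"):
            if col not in df.columns:
                raise ValueError(f"{path}: measurement matrix missing {col!r} column")
        bmi = df.pop("bmi").astype(float)
        group = df.pop("group").astype(str)
        return cls(df.astype(float), bmi, group)


def compute_measurement_matrix(
    subjects: Sequence[tuple[SubjectRecord, FAVolume]],
    atlas: AtlasVolume,
    panel: Sequence[str] = DEFAULT_PANEL,
) -> TractMeasurementMatrix:
    """Assemble the measurement matrix: one row per subject, one column per
    (tract, statistic) in atlas-table order x panel order.

    A subject with an empty tract yields NaN in that tract's columns (count
    logged); all volumes must share the atlas grid.
    """
    panel = list(panel)
    unknown = [s for s in panel if s not in STATISTIC_NAMES]
    if unknown:
        raise ValueError(f"unknown statistics in panel: {unknown}")
    labels = sorted(atlas.label_table)
    columns = [column_id(atlas.label_table[lab], s) for lab in labels for s in panel]
    rows: dict[str, list[float]] = {}
    bmi: dict[str, float] = {}
    group: dict[str, str] = {}
    n_missing = 0
    for record, volume in subjects:
        values: list[float] = []
        for lab in labels:
            vox = extract_tract_voxels(volume, atlas, lab)
            if vox.size == 0:
                n_missing += len(panel)
                values.extend([float("nan")] * len(panel))
            else:
                values.extend(compute_statistic(vox, s) for s in panel)
        rows[record.subject_id] = values
        bmi[record.subject_id] = record.bmi
        group[record.subject_id] = record.group
    if n_missing:
        logger.warning("%d measurement cells missing (empty tracts)", n_missing)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    data.index.name = "subject_id"
    return TractMeasurementMatrix(
        data, pd.Series(bmi, name="bmi"), pd.Series(group, name="group")
    )
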