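"""Biomarker matrices: tract x statistic coefficient grids plus a constant.

A fitted linear model over (tract, statistic) measurement columns is
re-expressed as a numerical matrix with the regression coefficients placed
at their (tract, statistic) cells and zeros elsewhere.  Applying the
biomarker to a subject's measurement grid is the element-wise product
summation of the two matrices plus the model constant (c_q for BMI
quantification, c_c for classification, where the caller hardens the
output s at 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_search import CLASSIFICATION, REGRESSION, LinearModel
from .tract_statistics import TractMeasurementMatrix, column_id, split_column_id


@dataclass
class BiomarkerMatrix:
    """Coefficient grid (rows = tracts, columns = statistics) + constant."""

    tracts: list[str]
    statistics: list[str]
    grid: np.ndarray
    constant: float
    task: str
    provenance: dict | None = None
    #: Source-model feature order; kept so applying the biomarker reproduces
    #: the model's predictions bit for bit (summation order matters).
    feature_order: list[str] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (len(self.tracts), len(self.statistics)):
            raise ValueError(
                f"grid shape {self.grid.shape} != ({len(self.tracts)}, {len(self.statistics)})"
            )
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def nonzero_cells(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.grid)
        return [(self.tracts[i], self.statistics[j]) for i, j in zip(rows, cols)]

    # -- serialization ------------------------------------------------------

    def save(self, grid_path: str | Path, sidecar_path: str | Path) -> None:
        """CSV grid plus JSON sidecar; coefficients kept to 17 significant
        digits so the round-trip is bit-faithful."""
        df = pd.DataFrame(self.grid, index=self.tracts, columns=self.statistics)
        df.index.name = "tract"
        df.to_csv(grid_path, float_format="%.17g")
        sidecar = {
            "task": self.task,
            "constant": self.constant,
            "statistics": self.statistics,
            "tracts": self.tracts,
            "feature_order": self.feature_order,
            "provenance": self.provenance or {},
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, grid_path: str | Path, sidecar_path: str | Path) -> "BiomarkerMatrix":
        meta = json.loads(Path(sidecar_path).read_text())
        df = pd.read_csv(grid_path, index_col="tract", float_precision="round_trip")
        df = df.loc[meta["tracts"], meta["statistics"]]
        return cls(meta["tracts"], meta["statistics"], df.to_numpy(dtype=float),
                   float(meta["constant"]), meta["task"], meta.get("provenance"),
                   meta.get("feature_order"))

    def to_model(self) -> LinearModel:
        """The equivalent linear model (inverse of assemble_biomarker).

        Features come back in the source model's order when it was recorded,
        otherwise in row-major grid order.
        """
        cell_coef = {column_id(t, s): float(self.grid[self.tracts.index(t), self.statistics.index(s)])
                     for t, s in self.nonzero_cells}
        if self.feature_order is not None:
            features = [f for f in self.feature_order if f in cell_coef]
            features += [f for f in cell_coef if f not in features]
        else:
            features = list(cell_coef)
        return LinearModel(self.task, features, [cell_coef[f] for f in features],
                           self.constant)


def assemble_biomarker(
    model: LinearModel,
    statistics: Sequence[str],
    tracts: Sequence[str],
    provenance: dict | None = None,
) -> BiomarkerMatrix:
    """Place the model's coefficients on the tract x statistic grid."""
    tracts = list(tracts)
    statistics = list(statistics)
    grid = np.zeros((len(tracts), len(statistics)))
    for feat, coef in zip(model.features, model.coefficients):
        tract, stat = split_column_id(feat)
        if tract not in tracts or stat not in statistics:
            raise ValueError(f"feature {feat!r} outside the biomarker grid")
        grid[tracts.index(tract), statistics.index(stat)] = coef
    return BiomarkerMatrix(tracts, statistics, grid, model.intercept, model.task,
                           provenance, feature_order=list(model.features))


def apply_biomarker(bm: BiomarkerMatrix, subject_grid: np.ndarray | pd.DataFrame) -> float:
    """Element-wise product summation with the subject's measurement grid,
    plus the model constant.

    NaN measurements are allowed only at zero-coefficient cells.  The
    product is accumulated in the source model's feature order so the result
    equals predicting with that model exactly.
    """
    if isinstance(subject_grid, pd.DataFrame):
        subject_grid = subject_grid.loc[bm.tracts, bm.statistics].to_numpy(dtype=float)
    subject_grid = np.asarray(subject_grid, dtype=float)
    if subject_grid.shape != bm.grid.shape:
        raise ValueError(f"subject grid shape {subject_grid.shape} != {bm.grid.shape}")
    mask = bm.grid != 0
    if np.any(~np.isfinite(subject_grid[mask])):
        raise ValueError("missing measurement at a nonzero biomarker cell")
    model = bm.to_model()
    cell_value = {}
    for i, tract in enumerate(bm.tracts):
        for j, stat in enumerate(bm.statistics):
            cell_value[column_id(tract, stat)] = subject_grid[i, j]
    x = np.array([[cell_value[f] for f in model.features]])
    return float((x @ np.asarray(model.coefficients) + model.intercept)[0])


def subject_grid_from_matrix(
    matrix: TractMeasurementMatrix, subject_id: str, bm: BiomarkerMatrix
) -> np.ndarray:
    """One subject's measurements arranged on the biomarker's grid."""
    grid = np.full(bm.grid.shape, np.nan)
    row = matrix.data.loc[subject_id]
    for i, tract in enumerate(bm.tracts):
        for j, stat in enumerate(bm.statistics):
            col = column_id(tract, stat)
            if col in row.index:
                grid[i, j] = row[col]
    return grid


def apply_biomarker_to_matrix(
    bm: BiomarkerMatrix, matrix: TractMeasurementMatrix
) -> pd.Series:
    """Predictions for every subject in a measurement matrix (exactly equal
    to predicting with the source linear model)."""
    model = bm.to_model()
    missing = [f for f in model.features if f not in matrix.data.columns]
    if missing:
        raise KeyError(f"matrix missing biomarker cells: {missing}")
    X = matrix.data[model.features].to_numpy(dtype=float)
    values = X @ np.asarray(model.coefficients) + model.intercept
    return pd.Series(values, index=matrix.data.index, name="prediction")
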