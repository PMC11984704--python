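"""Synthetic cohorts with planted BMI effects for end-to-end testing.

The generator emulates the statistical structure the analysis assumes: a
two-group cohort (80 normal-weight subjects with integer BMI 19-24 and 80
overweight/obese subjects with integer BMI 25-47, the OB side weighted
49/19/12 across the 25-29 / 30-34 / 35-47 bands), measurement columns with
configurable linear BMI effects plus Gaussian noise, and — in image mode —
small toy FA volumes over a block-label atlas that induce those effects
through the statistics stage.  It does not emulate diffusion physics or
anatomy; see the methods note for what passing tests do and do not show.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging_io import (
    AtlasVolume,
    FAVolume,
    SubjectRecord,
    icbm_dti81_label_table,
    write_atlas,
    write_fa_volume,
    write_subject_table,
)
from .model_search import LinearModel
from .screening import ScreeningResult
from .tract_statistics import (
    DEFAULT_PANEL,
    TractMeasurementMatrix,
    column_id,
)

logger = logging.getLogger(__name__)

#: Band weighting of the OB group mimicking the study cohort's composition:
#: (low BMI, high BMI, weight) for overweight / obese / extremely obese.
DEFAULT_OB_BANDS: tuple[tuple[int, int, int], ...] = (
    (25, 29, 49),
    (30, 34, 19),
    (35, 47, 12),
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``planted_columns`` maps column id -> effect size beta (units of the
    measurement per kg/m^2); None selects ``n_planted`` columns at random
    with alternating-sign effects of magnitude ``planted_beta``.  Matrix
    mode draws measurement columns directly; image mode synthesizes FA
    volumes over a block atlas whose planted tracts shift with BMI.
    """

    n_nw: int = 80
    n_ob: int = 80
    nw_bmi_range: tuple[int, int] = (19, 24)
    ob_bands: tuple[tuple[int, int, int], ...] = DEFAULT_OB_BANDS
    n_tracts: int = 50
    panel: tuple[str, ...] = DEFAULT_PANEL
    n_planted: int = 10
    planted_beta: float = 0.002
    planted_columns: dict[str, float] | None = None
    noise_sd: float = 0.01
    mode: str = "matrix"  # "matrix" | "image"
    shape: tuple[int, int, int] = (24, 24, 24)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("matrix", "image"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth: column id -> beta (and tract-level betas in
    image mode, where a planted tract's central-tendency columns carry the
    effect)."""

    planted_columns: dict[str, float]
    planted_tracts: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    truth: SyntheticTruth
    config: GeneratorConfig
    matrix: TractMeasurementMatrix | None = None
    volumes: list[FAVolume] | None = None
    atlas: AtlasVolume | None = None

    def write(self, out_dir: str | Path) -> None:
        """Write the same CSV/NIfTI/TSV formats the real-data path reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_subject_table(self.subjects, out / "subjects.csv")
        if self.matrix is not None:
            self.matrix.to_csv(out / "measurements.csv")
        if self.volumes is not None and self.atlas is not None:
            write_atlas(self.atlas, out / "atlas.nii.gz", out / "labels.tsv")
            vol_dir = out / "fa"
            vol_dir.mkdir(exist_ok=True)
            for vol in self.volumes:
                write_fa_volume(vol, vol_dir / f"{vol.subject_id}.nii.gz")


def _tract_names(n_tracts: int) -> list[str]:
    table = icbm_dti81_label_table()
    if n_tracts <= len(table):
        return [table[k] for k in sorted(table)[:n_tracts]]
    return [f"tract_{i:02d}" for i in range(1, n_tracts + 1)]


def _sample_bmi(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.nw_bmi_range
    nw = rng.integers(lo, hi + 1, size=config.n_nw)
    weights = np.array([b[2] for b in config.ob_bands], dtype=float)
    weights /= weights.sum()
    bands = rng.choice(len(config.ob_bands), size=config.n_ob, p=weights)
    ob = np.array([
        rng.integers(config.ob_bands[b][0], config.ob_bands[b][1] + 1) for b in bands
    ])
    return np.concatenate([nw, ob]).astype(float)


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> SyntheticCohort:
    """Generate a deterministic (per seed) synthetic cohort.

    Matrix mode: x_ij = mu_j + beta_j (BMI_i - mean BMI) + eps with
    eps ~ N(0, noise_sd^2) and beta_j = 0 for non-planted columns.  Image
    mode: planted tracts' voxel FA is Beta-distributed with a location
    shifting linearly with BMI; other tracts are BMI-independent.
    """
    rng = np.random.default_rng(config.seed)
    bmi = _sample_bmi(config, rng)
    subjects = [
        SubjectRecord.from_bmi(f"sub-{i:04d}", float(b)) for i, b in enumerate(bmi)
    ]
    tracts = _tract_names(config.n_tracts)
    if config.mode == "matrix":
        return _generate_matrix_mode(config, rng, subjects, bmi, tracts)
    return _generate_image_mode(config, rng, subjects, bmi, tracts)


def _resolve_planted(config: GeneratorConfig, rng: np.random.Generator,
                     columns: list[str]) -> dict[str, float]:
    if config.planted_columns is not None:
        missing = [c for c in config.planted_columns if c not in columns]
        if missing:
            raise ValueError(f"planted columns not in design: {missing}")
        return dict(config.planted_columns)
    picks = rng.choice(len(columns), size=config.n_planted, replace=False)
    return {
        columns[p]: config.planted_beta * (1 if i % 2 == 0 else -1)
        for i, p in enumerate(sorted(picks))
    }


def _generate_matrix_mode(config, rng, subjects, bmi, tracts) -> SyntheticCohort:
    columns = [column_id(t, s) for t in tracts for s in config.panel]
    planted = _resolve_planted(config, rng, columns)
    mu = rng.uniform(0.3, 0.6, size=len(columns))
    centered = bmi - bmi.mean()
    values = np.empty((len(subjects), len(columns)))
    for j, col in enumerate(columns):
        beta = planted.get(col, 0.0)
        values[:, j] = mu[j] + beta * centered + rng.normal(0, config.noise_sd, len(subjects))
    data = pd.DataFrame(values, index=[s.subject_id for s in subjects], columns=columns)
    data.index.name = "subject_id"
    matrix = TractMeasurementMatrix(
        data,
        pd.Series(bmi, index=data.index, name="bmi"),
        pd.Series([s.group for s in subjects], index=data.index, name="group"),
    )
    return SyntheticCohort(subjects, SyntheticTruth(planted), config, matrix=matrix)


#: Central-tendency statistics through which an image-mode location shift is
#: expected to surface in the measurement matrix.
CENTRAL_TENDENCY = ("arithmetic_mean", "median", "geometric_mean", "harmonic_mean")


def _block_atlas(config: GeneratorConfig, tracts: list[str]) -> AtlasVolume:
    """Disjoint cubic blocks, one per tract, on a margin-separated grid."""
    shape = config.shape
    per_axis = max(1, min(shape) // 6)
    if per_axis**3 < len(tracts):
        raise ValueError(
            f"geometry {shape} fits {per_axis ** 3} disjoint blocks, "
            f"need {len(tracts)}"
        )
    labels = np.zeros(shape, dtype=np.int64)
    cells = [(i, j, k) for i in range(per_axis) for j in range(per_axis) for k in range(per_axis)]
    for label, (i, j, k) in enumerate(cells[: len(tracts)], start=1):
        labels[6 * i + 1 : 6 * i + 5, 6 * j + 1 : 6 * j + 5, 6 * k + 1 : 6 * k + 5] = label
    return AtlasVolume(labels, {i + 1: t for i, t in enumerate(tracts)})


def _generate_image_mode(config, rng, subjects, bmi, tracts) -> SyntheticCohort:
    atlas = _block_atlas(config, tracts)
    n_planted_tracts = min(config.n_planted, len(tracts))
    pick = sorted(rng.choice(len(tracts), size=n_planted_tracts, replace=False))
    tract_beta = {
        tracts[p]: config.planted_beta * (1 if i % 2 == 0 else -1)
        for i, p in enumerate(pick)
    }
    base_mu = {t: rng.uniform(0.35, 0.55) for t in tracts}
    concentration = 60.0  # Beta distribution a+b; higher = tighter voxel spread
    centered = bmi - bmi.mean()

    volumes = []
    for subj, c in zip(subjects, centered):
        vox = np.zeros(config.shape, dtype=float)
        for label, tract in atlas.label_table.items():
            mask = atlas.labels == label
            mu = base_mu[tract] + tract_beta.get(tract, 0.0) * c
            mu = float(np.clip(mu, 0.05, 0.95))
            a, b = mu * concentration, (1 - mu) * concentration
            vox[mask] = rng.beta(a, b, size=int(mask.sum()))
        volumes.append(FAVolume(vox, subject_id=subj.subject_id))

    planted_cols = {
        column_id(t, s): beta
        for t, beta in tract_beta.items()
        for s in CENTRAL_TENDENCY
        if s in config.panel
    }
    truth = SyntheticTruth(planted_cols, planted_tracts=tract_beta)
    return SyntheticCohort(subjects, truth, config, volumes=volumes, atlas=atlas)


# ---------------------------------------------------------------------------
# Ground-truth recovery
# ---------------------------------------------------------------------------

def hypergeom_enrichment_p(
    n_universe: int, n_planted: int, n_selected: int, n_overlap: int
) -> float:
    """Upper-tail hypergeometric probability of >= n_overlap planted columns
    among n_selected drawn from a universe containing n_planted."""
    return float(sps.hypergeom.sf(n_overlap - 1, n_universe, n_planted, n_selected))


def truth_recovery_report(
    result: ScreeningResult | LinearModel,
    truth: SyntheticTruth,
    universe: Sequence[str],
) -> dict:
    """True/false positives of a screening result or fitted model against
    the planted columns, with a hypergeometric enrichment p-value."""
    if isinstance(result, ScreeningResult):
        selected = set(result.chosen_columns)
        if not set(result.table["column"]) == set(universe):
            raise ValueError("screening result and universe refer to different columns")
    else:
        selected = set(result.features)
        stray = selected - set(universe)
        if stray:
            raise ValueError(f"model features outside the universe: {sorted(stray)}")
    planted = set(truth.planted_columns)
    if not planted <= set(universe):
        raise ValueError("truth columns are not a subset of the universe")
    tp = len(selected & planted)
    fp = len(selected - planted)
    return {
        "true_positives": tp,
        "false_positives": fp,
        "n_selected": len(selected),
        "n_planted": len(planted),
        "recall": tp / len(planted) if planted else float("nan"),
        "enrichment_p": hypergeom_enrichment_p(
            len(universe), len(planted), len(selected), tp
        ),
    }
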