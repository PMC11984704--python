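"""Two-condition screening of tract measurements.

Condition one: the measurement differs between the normal-weight and
overweight/obese groups by a two-sided Wilcoxon rank-sum test (p_w < alpha,
uncorrected).  Condition two: the measurement's Spearman correlation with
BMI over the whole cohort is significant after Benjamini-Hochberg FDR
correction across the full column family (adjusted p_c < alpha).
Measurements meeting both are "chosen"; their count is N.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .imaging_io import NW, OB
from .tract_statistics import TractMeasurementMatrix

logger = logging.getLogger(__name__)

#: Both groups at or below this size use exact rank-sum enumeration.
EXACT_MAX_N = 8


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float], method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value with midranks for ties.

    ``auto`` uses exact enumeration of all group assignments when both
    groups have at most 8 observations and otherwise a tie-corrected normal
    approximation with continuity correction (the Mann-Whitney U asymptotic
    path); ``exact`` and ``approx`` force one path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" or (
        method == "auto" and x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N
    ):
        return _exact_rank_sum_p(x, y)
    # Mann-Whitney U and the rank-sum statistic are equivalent tests.
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all C(n1+n2, n1) rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    n1, n = x.size, pooled.size
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = 0
    total = comb(n, n1)
    for idx in itertools.combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def spearman_with_bmi(
    x: Sequence[float], bmi: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho (Pearson correlation of midranks) and its two-sided
    p-value from the t approximation with n-2 degrees of freedom.

    Returns (nan, nan) for a constant input vector (rho undefined); callers
    flag and exclude such columns.
    """
    x = np.asarray(x, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if x.size != bmi.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(bmi) == 0:
        return float("nan"), float("nan")
    res = sps.spearmanr(x, bmi)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreeningResult:
    """Per-column screening records plus the chosen count N.

    ``table`` has one row per measurement column with fields
    column, p_w, rho, p_c_raw, p_c_adj, passes_c1, passes_c2, chosen,
    excluded (missing or constant columns, never chosen).
    """

    table: pd.DataFrame
    alpha: float

    @property
    def N(self) -> int:
        return int(self.table["chosen"].sum())

    @property
    def family_size(self) -> int:
        return int((~self.table["excluded"]).sum())

    @property
    def chosen_columns(self) -> list[str]:
        return self.table.loc[self.table["chosen"], "column"].tolist()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {"N": self.N, "alpha": self.alpha, "family_size": self.family_size}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, alpha: float) -> "ScreeningResult":
        return cls(pd.read_csv(path), alpha)


def choose_measurements(
    matrix: TractMeasurementMatrix, alpha: float = 0.05
) -> ScreeningResult:
    """Apply both screening conditions to every measurement column.

    Columns with missing values or constant values are excluded from the
    analysis (and from the FDR family) with a logged count.  Both conditions
    use strict inequality against ``alpha``.
    """
    groups = matrix.group
    nw_mask = (groups == NW).to_numpy()
    ob_mask = (groups == OB).to_numpy()
    if nw_mask.sum() < 2 or ob_mask.sum() < 2:
        raise ValueError("both NW and OB groups (>=2 subjects each) are required")
    bmi = matrix.bmi.to_numpy(dtype=float)

    records = []
    for col in matrix.columns:
        v = matrix.data[col].to_numpy(dtype=float)
        excluded = bool(np.any(~np.isfinite(v)) or np.ptp(v) == 0)
        if excluded:
            records.append((col, np.nan, np.nan, np.nan, True))
            continue
        p_w = wilcoxon_rank_sum(v[nw_mask], v[ob_mask])
        rho, p_c_raw = spearman_with_bmi(v, bmi)
        if not np.isfinite(rho):
            records.append((col, np.nan, np.nan, np.nan, True))
            continue
        records.append((col, p_w, rho, p_c_raw, False))

    df = pd.DataFrame(records, columns=["column", "p_w", "rho", "p_c_raw", "excluded"])
    n_excl = int(df["excluded"].sum())
    if n_excl:
        logger.warning("%d columns excluded from screening (missing/constant)", n_excl)

    df["p_c_adj"] = np.nan
    family = ~df["excluded"]
    if family.any():
        df.loc[family, "p_c_adj"] = fdr_adjust(df.loc[family, "p_c_raw"].to_numpy())
    df["passes_c1"] = family & (df["p_w"] < alpha)
    df["passes_c2"] = family & (df["p_c_adj"] < alpha)
    df["chosen"] = df["passes_c1"] & df["passes_c2"]
    df = df[
        ["column", "p_w", "rho", "p_c_raw", "p_c_adj",
         "passes_c1", "passes_c2", "chosen", "excluded"]
    ]
    result = ScreeningResult(df, alpha)
    logger.info("screening: N=%d of %d columns chosen (alpha=%g)",
                result.N, len(df), alpha)
    return result
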