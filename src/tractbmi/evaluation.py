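"""Performance metrics for the quantification and classification models.

Regression: Pearson correlation with Fisher-z confidence interval and
t-based p-value, RMSE, MAPE, and Bland-Altman agreement (reproducibility
coefficient RPC = 1.96 x SD of the paired differences, and a coefficient of
variation).  Classification: sensitivity, specificity and accuracy at the
0 threshold on -1/+1 codes, each accompanied by the RMSE and MAPE between
the +-1 actual and hardened predicted labels over that metric's row subset
(so for a rate a, RMSE = 2 sqrt(1-a) and MAPE = 200 (1-a) %).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .model_search import harden


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation:
    tanh(atanh(r) +- z* / sqrt(n-3))."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    zq = sps.norm.ppf(0.5 + level / 2.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    return float(np.tanh(z - zq * se)), float(np.tanh(z + zq * se))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation from the t statistic with
    n-2 degrees of freedom."""
    with np.errstate(divide="ignore"):
        t = abs(r) * np.sqrt((n - 2) / max(1 - r**2, 0.0)) if abs(r) < 1 else np.inf
    return float(2 * sps.t.sf(t, n - 2))


def pearson_with_ci(
    actual: Sequence[float], predicted: Sequence[float], level: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """Pearson r, Fisher-z confidence interval and two-sided p-value."""
    a = np.asarray(actual, dtype=float)
    b = np.asarray(predicted, dtype=float)
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, fisher_ci(r, n, level), correlation_pvalue(r, n)


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def mape(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("length mismatch")
    if np.any(a == 0):
        raise ValueError("MAPE undefined for zero actual values")
    return float(np.mean(np.abs(a - p) / np.abs(a)) * 100.0)


def bland_altman(actual: Sequence[float], predicted: Sequence[float]) -> dict:
    """Bland-Altman agreement of predicted against actual values.

    Differences d = predicted - actual; RPC = 1.96 x sample SD of d; the
    coefficient of variation is the SD of d as a percentage of the mean of
    the paired means.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = p - a
    sd = float(np.std(d, ddof=1))
    mean_of_means = float(np.mean((a + p) / 2.0))
    return {
        "mean_diff": float(np.mean(d)),
        "sd_diff": sd,
        "rpc": 1.96 * sd,
        "cv": 100.0 * sd / mean_of_means if mean_of_means != 0 else float("nan"),
    }


def regression_metrics(actual: Sequence[float], predicted: Sequence[float]) -> dict:
    """The full per-subset regression panel (r, CI, p, RMSE, MAPE, Bland-Altman)."""
    r, ci, p = pearson_with_ci(actual, predicted)
    return {
        "pearson_r": r,
        "ci95": list(ci),
        "p_p": p,
        "rmse": rmse(actual, predicted),
        "mape": mape(actual, predicted),
        "bland_altman": bland_altman(actual, predicted),
    }


def classification_metrics(
    actual_labels: Sequence[int], scores: Sequence[float], threshold: float = 0.0
) -> dict:
    """Sensitivity/specificity/accuracy with the +-1-label error convention.

    ``actual_labels`` are -1/+1 with OB = +1 the positive class; ``scores``
    are raw model outputs hardened at ``threshold`` (ties to -1).  For each
    rate the RMSE and MAPE are computed between the actual and hardened
    labels over that rate's own row subset.  A class absent from the data
    leaves its metrics NaN.
    """
    y = np.asarray(actual_labels)
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be coded -1/+1")
    pred = harden(np.asarray(scores, dtype=float) - threshold)

    def _panel(mask: np.ndarray) -> dict:
        if not mask.any():
            return {"rate": float("nan"), "rmse": float("nan"), "mape": float("nan")}
        a, p = y[mask], pred[mask]
        rate = float(np.mean(a == p))
        return {
            "rate": rate,
            "rmse": rmse(a.astype(float), p.astype(float)),
            "mape": mape(a.astype(float), p.astype(float)),
            "n": int(mask.sum()),
        }

    return {
        "sensitivity": _panel(y == 1),
        "specificity": _panel(y == -1),
        "accuracy": _panel(np.ones_like(y, dtype=bool)),
    }


# ---------------------------------------------------------------------------
# Report assembly / serialization
# ---------------------------------------------------------------------------

SUBSETS = ("train", "val", "test")


def build_regression_report(per_subset: dict[str, tuple[Sequence[float], Sequence[float]]]) -> dict:
    """Map subset name -> (actual BMI, predicted BMI) to the full report."""
    return {name: regression_metrics(a, p) for name, (a, p) in per_subset.items()}


def build_classification_report(per_subset: dict[str, tuple[Sequence[int], Sequence[float]]]) -> dict:
    """Map subset name -> (actual labels, raw scores) to the full report."""
    return {name: classification_metrics(y, s) for name, (y, s) in per_subset.items()}


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def format_regression_report(report: dict) -> str:
    """Human-readable table mirroring the regression results layout."""
    lines = [f"{'Subset':<10} {'r':>8} {'95% CI':>20} {'p':>10} {'RMSE':>8} {'MAPE':>8} {'RPC':>7} {'CV':>6}"]
    for name, m in report.items():
        lo, hi = m["ci95"]
        ba = m["bland_altman"]
        lines.append(
            f"{name:<10} {m['pearson_r']:>8.4f} ({lo:.4f}, {hi:.4f})"
            f" {m['p_p']:>10.2e} {m['rmse']:>7.2f} {m['mape']:>7.2f}%"
            f" {ba['rpc']:>7.2f} {ba['cv']:>5.1f}%"
        )
    return "\n".join(lines)


def format_classification_report(report: dict) -> str:
    lines = [f"{'Subset':<10} {'Sens':>7} {'RMSE':>7} {'MAPE':>7} {'Spec':>7} {'RMSE':>7} {'MAPE':>7} {'Acc':>7} {'RMSE':>7} {'MAPE':>7}"]
    for name, m in report.items():
        row = [f"{name:<10}"]
        for key in ("sensitivity", "specificity", "accuracy"):
            row.append(f"{m[key]['rate']:>7.4f} {m[key]['rmse']:>7.3f} {m[key]['mape']:>6.1f}%")
        lines.append(" ".join(row))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Optional figures
# ---------------------------------------------------------------------------

def plot_regression(report_inputs: dict, path: str | Path) -> None:
    """Correlation + Bland-Altman panels per subset (static matplotlib file)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(report_inputs)
    fig, axes = plt.subplots(2, len(names), figsize=(4 * len(names), 7), squeeze=False)
    for j, name in enumerate(names):
        a, p = (np.asarray(v, float) for v in report_inputs[name])
        ax = axes[0][j]
        ax.scatter(a, p, s=12)
        lim = [min(a.min(), p.min()), max(a.max(), p.max())]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set(title=name, xlabel="actual BMI", ylabel="predicted BMI")
        ba = bland_altman(a, p)
        ax = axes[1][j]
        means, diffs = (a + p) / 2, p - a
        ax.scatter(means, diffs, s=12)
        for y, style in ((ba["mean_diff"], "-"), (ba["mean_diff"] + ba["rpc"], "--"),
                         (ba["mean_diff"] - ba["rpc"], "--")):
            ax.axhline(y, color="r", ls=style, lw=0.8)
        ax.set(xlabel="mean of pair", ylabel="difference")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_classification(report_inputs: dict, path: str | Path) -> None:
    """Raw-score strip per subset with the 0 decision threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(report_inputs)
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.5), squeeze=False)
    for j, name in enumerate(names):
        y, s = report_inputs[name]
        y = np.asarray(y)
        s = np.asarray(s, float)
        ax = axes[0][j]
        x = np.arange(s.size)
        ax.scatter(x[y == -1], s[y == -1], c="green", s=14, label="NW")
        ax.scatter(x[y == 1], s[y == 1], c="red", s=14, label="OB")
        ax.axhline(0, color="k", ls=":")
        ax.set(title=name, xlabel="subject", ylabel="model output s")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
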