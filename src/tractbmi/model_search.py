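"""Randomized add/exclude stepwise search for linear biomarker models.

The search builds a multiple linear regression over screened tract
measurements.  Starting from a single randomly drawn measurement, it
alternately tries to ADD and then EXCLUDE from 1 to k_max measurements at a
time, accepting a change only when the mean of the training and validation
scores strictly improves the incumbent (r_mean > r_mean* for BMI
quantification, a_mean > a_mean* for NW/OB classification).  Each
acceptance is a "step"; rejected candidates are set aside until the next
acceptance resets the pool.  The whole procedure is restarted many times
from independent random seeds and the best incumbent across restarts wins.

Two tasks share the machinery: ``regression`` predicts BMI and is scored by
the Pearson correlation between actual and predicted values; ``classification``
predicts the -1/+1 weight-category code, hardened at a threshold of 0, and
is scored by accuracy.
"""

from __future__ import annotations

import csv
import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort_split import CohortSplit
from .tract_statistics import TractMeasurementMatrix

REGRESSION = "regression"
CLASSIFICATION = "classification"

NEG_INF = float("-inf")


@dataclass
class LinearModel:
    """An ordinary-least-squares linear model over measurement columns."""

    task: str
    features: list[str]
    coefficients: list[float]
    intercept: float

    def __post_init__(self) -> None:
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task {self.task!r}")
        if len(set(self.features)) != len(self.features):
            raise ValueError("model features must be distinct")
        if len(self.coefficients) != len(self.features):
            raise ValueError("one coefficient per feature required")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ScorePair:
    """Training and validation scores and their arithmetic mean."""

    train_score: float
    val_score: float

    @property
    def mean_score(self) -> float:
        return (self.train_score + self.val_score) / 2.0


@dataclass
class SearchStep:
    step: int
    action: str  # "add" | "exclude"
    k: int
    accepted: list[str]
    model_size: int
    train_score: float
    val_score: float
    mean_score: float


@dataclass
class SearchTrace:
    """Accepted-step history of the winning restart."""

    steps: list[SearchStep]
    restarts_done: int
    best_restart: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "restarts_done": self.restarts_done,
                    "best_restart": self.best_restart,
                    "steps": [asdict(s) for s in self.steps],
                },
                indent=2,
            )
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "action", "k", "m", "train_score", "val_score", "mean_score"])
            for s in self.steps:
                w.writerow([s.step, s.action, s.k, s.model_size,
                            s.train_score, s.val_score, s.mean_score])


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the stepwise search.

    ``k_max`` is the largest group of measurements added or excluded at
    once; ``restarts`` the number of independent randomized repetitions;
    ``max_model_size`` defaults to n_train - 2 to keep the fit
    over-determined; ``exhaustive_subsets`` sweeps all C(pool, k) subsets
    for k > 1 instead of a random disjoint partition (affordable only for
    tiny candidate pools).
    """

    k_max: int = 5
    restarts: int = 1000
    seed: int = 0
    max_model_size: int | None = None
    exhaustive_subsets: bool = False

    def __post_init__(self) -> None:
        if self.k_max < 1 or self.restarts < 1:
            raise ValueError("k_max and restarts must be >= 1")


# ---------------------------------------------------------------------------
# Fitting and scoring
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-norm least squares fit with intercept; deterministic."""
    A = np.column_stack([X, np.ones(len(X))])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return sol[:-1], float(sol[-1])


def fit_linear(
    features: Sequence[str],
    train_rows: TractMeasurementMatrix,
    targets: Sequence[float],
    task: str = REGRESSION,
) -> LinearModel:
    """Ordinary least-squares fit of ``targets`` on the given columns.

    Rank-deficient designs are solved by minimum-norm least squares, so a
    duplicated column yields the same predictions as the single-column fit.
    """
    features = list(features)
    if train_rows.n_subjects < 2:
        raise ValueError("need at least 2 training rows")
    X = train_rows.data[features].to_numpy(dtype=float)
    coefs, intercept = _ols(X, np.asarray(targets, dtype=float))
    return LinearModel(task, features, [float(c) for c in coefs], intercept)


def predict(model: LinearModel, rows: TractMeasurementMatrix) -> np.ndarray:
    """Linear combination plus intercept; for classification this is the raw
    score s, hardened by the caller at threshold 0."""
    missing = [f for f in model.features if f not in rows.data.columns]
    if missing:
        raise KeyError(f"rows missing model features: {missing}")
    X = rows.data[model.features].to_numpy(dtype=float)
    return X @ np.asarray(model.coefficients) + model.intercept


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return NEG_INF  # degenerate; never an improvement
    return float(np.corrcoef(a, b)[0, 1])


def harden(scores: np.ndarray) -> np.ndarray:
    """Raw model outputs to -1/+1 class codes; s == 0 goes to NW (-1)."""
    return np.where(np.asarray(scores) > 0, 1, -1)


def _accuracy(labels: np.ndarray, scores: np.ndarray) -> float:
    return float(np.mean(harden(scores) == labels))


def score_regression(
    model: LinearModel,
    train_rows: TractMeasurementMatrix, train_bmi: np.ndarray,
    val_rows: TractMeasurementMatrix, val_bmi: np.ndarray,
) -> ScorePair:
    """Pearson r of actual vs predicted BMI on train and validation."""
    r_tr = _pearson(np.asarray(train_bmi, float), predict(model, train_rows))
    r_val = _pearson(np.asarray(val_bmi, float), predict(model, val_rows))
    return ScorePair(r_tr, r_val)


def score_classification(
    model: LinearModel,
    train_rows: TractMeasurementMatrix, train_labels: np.ndarray,
    val_rows: TractMeasurementMatrix, val_labels: np.ndarray,
) -> ScorePair:
    """Fraction of subjects correctly classified on train and validation."""
    a_tr = _accuracy(np.asarray(train_labels), predict(model, train_rows))
    a_val = _accuracy(np.asarray(val_labels), predict(model, val_rows))
    return ScorePair(a_tr, a_val)


def group_labels(matrix: TractMeasurementMatrix, ids: Sequence[str]) -> np.ndarray:
    """-1/+1 coding of the NW/OB groups (OB = +1)."""
    return np.where(matrix.group.loc[list(ids)].to_numpy() == "OB", 1, -1)


# ---------------------------------------------------------------------------
# The search itself
# ---------------------------------------------------------------------------

class _Evaluator:
    """Fits and scores candidate feature sets on cached numpy arrays.

    Results are memoized per feature set: the fit is deterministic, so a
    subset revisited in a later restart costs a dict lookup.
    """

    def __init__(self, candidates: list[str], matrix: TractMeasurementMatrix,
                 split: CohortSplit, task: str, max_model_size: int):
        self.candidates = candidates
        self.task = task
        self.max_model_size = max_model_size
        self.Xtr = matrix.data.loc[split.train_ids, candidates].to_numpy(dtype=float)
        self.Xval = matrix.data.loc[split.val_ids, candidates].to_numpy(dtype=float)
        if task == REGRESSION:
            self.ytr = matrix.bmi.loc[split.train_ids].to_numpy(dtype=float)
            self.yval = matrix.bmi.loc[split.val_ids].to_numpy(dtype=float)
        else:
            self.ytr = group_labels(matrix, split.train_ids).astype(float)
            self.yval = group_labels(matrix, split.val_ids).astype(float)
        self._cache: dict[frozenset, tuple[np.ndarray, float, ScorePair]] = {}

    def evaluate(self, feats: frozenset) -> tuple[ScorePair, np.ndarray, float] | None:
        """Score a candidate feature set, or None if it exceeds the size cap."""
        if not feats or len(feats) > self.max_model_size:
            return None
        hit = self._cache.get(feats)
        if hit is None:
            idx = sorted(feats)
            coefs, intercept = _ols(self.Xtr[:, idx], self.ytr)
            pred_tr = self.Xtr[:, idx] @ coefs + intercept
            pred_val = self.Xval[:, idx] @ coefs + intercept
            if self.task == REGRESSION:
                pair = ScorePair(_pearson(self.ytr, pred_tr), _pearson(self.yval, pred_val))
            else:
                pair = ScorePair(_accuracy(self.ytr, pred_tr), _accuracy(self.yval, pred_val))
            hit = (coefs, intercept, pair)
            self._cache[feats] = hit
        coefs, intercept, pair = hit
        return pair, coefs, intercept


def _sweep_subsets(pool: list[int], k: int, rng: np.random.Generator,
                   exhaustive: bool):
    """Yield the k-subsets tried in one pass over ``pool``.

    Default: the pool is shuffled once and cut into disjoint consecutive
    k-subsets, so every measurement is considered once without repetition.
    Exhaustive mode enumerates all combinations in seeded random order.
    """
    if len(pool) < k:
        return
    if exhaustive and k > 1:
        combos = list(itertools.combinations(sorted(pool), k))
        order = rng.permutation(len(combos))
        for i in order:
            yield combos[i]
    else:
        order = list(pool)
        rng.shuffle(order)
        for i in range(0, len(order) - k + 1, k):
            yield tuple(order[i : i + k])


def _one_restart(ev: _Evaluator, rng: np.random.Generator,
                 k_max: int, exhaustive: bool) -> tuple[frozenset, ScorePair, list[SearchStep]]:
    n = len(ev.candidates)
    all_idx = list(range(n))

    # Seed model: one uniformly drawn candidate initializes the incumbent.
    seed_feat = int(rng.integers(n))
    incumbent = frozenset([seed_feat])
    pair, _, _ = ev.evaluate(incumbent)
    best = pair
    steps = [SearchStep(1, "add", 1, [ev.candidates[seed_feat]], 1,
                        pair.train_score, pair.val_score, pair.mean_score)]
    add_black: set[int] = set()
    excl_black: set[int] = set()

    while True:
        accepted = False
        for action in ("add", "exclude"):
            for k in range(1, k_max + 1):
                if action == "add":
                    pool = [i for i in all_idx if i not in incumbent and i not in add_black]
                else:
                    pool = [i for i in incumbent if i not in excl_black]
                for subset in _sweep_subsets(pool, k, rng, exhaustive):
                    if action == "add":
                        trial = incumbent | set(subset)
                    else:
                        trial = incumbent - set(subset)
                    result = ev.evaluate(trial)
                    if result is not None and result[0].mean_score > best.mean_score:
                        pair = result[0]
                        incumbent, best = trial, pair
                        steps.append(SearchStep(
                            len(steps) + 1, action, k,
                            [ev.candidates[i] for i in subset], len(incumbent),
                            pair.train_score, pair.val_score, pair.mean_score))
                        add_black.clear()
                        excl_black.clear()
                        accepted = True
                        break
                    (add_black if action == "add" else excl_black).update(subset)
                if accepted:
                    break
            if accepted:
                break
        if not accepted:
            return incumbent, best, steps


def run_search(
    candidates: Sequence[str],
    matrix: TractMeasurementMatrix,
    split: CohortSplit,
    task: str = REGRESSION,
    config: SearchConfig = SearchConfig(),
) -> tuple[LinearModel, SearchTrace]:
    """Run the full randomized add/exclude search and return the best model.

    Restarts use independent substreams (config.seed + restart index); the
    model with the highest incumbent mean score across restarts wins, with
    the earliest restart breaking exact ties.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    missing = [c for c in candidates if c not in matrix.data.columns]
    if missing:
        raise KeyError(f"candidates absent from matrix: {missing}")
    max_size = config.max_model_size
    if max_size is None:
        max_size = max(1, len(split.train_ids) - 2)
    ev = _Evaluator(candidates, matrix, split, task, max_size)

    best_feats: frozenset | None = None
    best_pair: ScorePair | None = None
    best_steps: list[SearchStep] = []
    best_restart = -1
    for restart in range(config.restarts):
        rng = np.random.default_rng(config.seed + restart)
        feats, pair, steps = _one_restart(ev, rng, config.k_max, config.exhaustive_subsets)
        if best_pair is None or pair.mean_score > best_pair.mean_score:
            best_feats, best_pair, best_steps, best_restart = feats, pair, steps, restart

    result = ev.evaluate(best_feats)
    assert result is not None
    _, coefs, intercept = result
    idx = sorted(best_feats)
    model = LinearModel(task, [candidates[i] for i in idx],
                        [float(c) for c in coefs], intercept)
    trace = SearchTrace(best_steps, config.restarts, best_restart)
    return model, trace
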