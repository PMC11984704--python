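"""OLS fitting, scoring, and the randomized add/exclude stepwise search."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

from tractbmi import (
    CLASSIFICATION,
    REGRESSION,
    LinearModel,
    SearchConfig,
    fit_linear,
    generate_cohort,
    group_labels,
    predict,
    run_search,
    score_classification,
    score_regression,
    stratified_split,
)
from tractbmi.synthetic_data import GeneratorConfig
from tractbmi.tract_statistics import TractMeasurementMatrix

import pandas as pd


def _matrix_from_array(X, bmi=None, group=None):
    cols = [f"t{j}|arithmetic_mean" for j in range(X.shape[1])]
    ids = [f"s{i}" for i in range(X.shape[0])]
    data = pd.DataFrame(X, index=ids, columns=cols)
    bmi = pd.Series(bmi if bmi is not None else np.zeros(len(ids)), index=ids)
    group = pd.Series(group if group is not None else ["NW"] * len(ids), index=ids)
    return TractMeasurementMatrix(data, bmi, group)


class TestFitAndPredict:
    def test_perfect_single_feature_fit(self):
        x = np.linspace(0, 1, 10)
        matrix = _matrix_from_array(x[:, None])
        model = fit_linear(matrix.columns, matrix, x)
        assert model.coefficients[0] == pytest.approx(1.0, abs=1e-10)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_column_same_predictions_as_single(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = 2 * x + rng.normal(0, 0.1, 12)
        single = _matrix_from_array(x[:, None])
        double = _matrix_from_array(np.column_stack([x, x]))
        m1 = fit_linear(single.columns, single, y)
        m2 = fit_linear(double.columns, double, y)
        assert np.allclose(predict(m1, single), predict(m2, double), atol=1e-8)

    def test_matches_independent_ols_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n, p = int(rng.integers(8, 30)), int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            matrix = _matrix_from_array(X)
            model = fit_linear(matrix.columns, matrix, y)
            oracle = sm.OLS(y, sm.add_constant(X)).fit()
            assert np.allclose(predict(model, matrix), oracle.fittedvalues, atol=1e-8)

    def test_zero_coefficients_predict_intercept(self):
        matrix = _matrix_from_array(np.random.default_rng(2).normal(size=(5, 2)))
        model = LinearModel(REGRESSION, matrix.columns, [0.0, 0.0], 3.5)
        assert np.allclose(predict(model, matrix), 3.5)

    def test_missing_feature_rejected(self):
        matrix = _matrix_from_array(np.zeros((4, 1)))
        model = LinearModel(REGRESSION, ["absent|median"], [1.0], 0.0)
        with pytest.raises(KeyError):
            predict(model, matrix)


class TestScoring:
    def test_regression_mean_is_arithmetic_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 1))
        y = X[:, 0] + rng.normal(0, 0.5, 20)
        m = _matrix_from_array(X, bmi=y)
        model = fit_linear(m.columns, m, y)
        pair = score_regression(model, m, y, m, y)
        assert pair.mean_score == pytest.approx((pair.train_score + pair.val_score) / 2)
        # r_train of an OLS fit equals sqrt(R^2) on the training data
        r2 = sm.OLS(y, sm.add_constant(X)).fit().rsquared
        assert pair.train_score == pytest.approx(np.sqrt(r2), abs=1e-10)

    def test_degenerate_predictions_score_neg_inf(self):
        m = _matrix_from_array(np.ones((6, 1)))
        model = LinearModel(REGRESSION, m.columns, [0.0], 1.0)
        pair = score_regression(model, m, np.arange(6.0), m, np.arange(6.0))
        assert pair.mean_score == float("-inf")

    def test_classification_counting_example(self):
        # 7 of 8 correct on train, 3 of 4 on val -> mean 0.8125
        Xtr = np.concatenate([-np.ones(4), np.ones(4)])[:, None]
        ytr = np.concatenate([-np.ones(4), np.ones(3), [-1.0]])
        Xval = np.concatenate([-np.ones(2), np.ones(2)])[:, None]
        yval = np.array([-1.0, -1.0, 1.0, -1.0])
        mtr, mval = _matrix_from_array(Xtr), _matrix_from_array(Xval)
        model = LinearModel(CLASSIFICATION, mtr.columns, [1.0], 0.0)
        pair = score_classification(model, mtr, ytr, mval, yval)
        assert pair.train_score == pytest.approx(0.875)
        assert pair.val_score == pytest.approx(0.75)
        assert pair.mean_score == pytest.approx(0.8125)

    def test_accuracy_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            labels = rng.choice([-1, 1], size=n)
            scores = rng.normal(size=n)
            hard = np.where(scores > 0, 1, -1)
            tp = np.sum((labels == 1) & (hard == 1))
            tn = np.sum((labels == -1) & (hard == -1))
            m = _matrix_from_array(scores[:, None])
            model = LinearModel(CLASSIFICATION, m.columns, [1.0], 0.0)
            pair = score_classification(model, m, labels, m, labels)
            assert pair.train_score == pytest.approx((tp + tn) / n)


def _search_problem(seed, n_cols=6, n_planted=2, noise=0.05):
    cfg = GeneratorConfig(n_nw=20, n_ob=20, n_tracts=max(1, n_cols // 3),
                          panel=("arithmetic_mean", "median", "maximum"),
                          n_planted=n_planted, noise_sd=noise, seed=seed)
    cohort = generate_cohort(cfg)
    split = stratified_split(cohort.subjects, (20, 10, 10), seed=seed + 1)
    return cohort, split


class TestRunSearch:
    def test_single_candidate_is_forced(self):
        cohort, split = _search_problem(seed=10)
        col = cohort.matrix.columns[0]
        model, trace = run_search([col], cohort.matrix, split, REGRESSION,
                                  SearchConfig(restarts=3, seed=0))
        assert model.features == [col]
        assert len(trace.steps) == 1

    def test_planted_perfect_predictor_found(self):
        cfg = GeneratorConfig(n_nw=10, n_ob=10, n_tracts=1,
                              panel=("arithmetic_mean", "median", "maximum"),
                              n_planted=1, noise_sd=0.0, seed=12)
        cohort = generate_cohort(cfg)
        split = stratified_split(cohort.subjects, (10, 5, 5), seed=2)
        planted = next(iter(cohort.truth.planted_columns))
        model, trace = run_search(cohort.matrix.columns, cohort.matrix, split,
                                  REGRESSION, SearchConfig(restarts=5, seed=1))
        assert planted in model.features
        assert trace.steps[-1].mean_score == pytest.approx(1.0, abs=1e-9)

    def test_trace_strictly_monotone_and_closed(self):
        cohort, split = _search_problem(seed=13)
        candidates = cohort.matrix.columns
        model, trace = run_search(candidates, cohort.matrix, split, REGRESSION,
                                  SearchConfig(restarts=10, seed=3))
        scores = [s.mean_score for s in trace.steps]
        assert all(b > a for a, b in zip(scores, scores[1:]))
        assert set(model.features) <= set(candidates)
        assert len(model.features) <= len(split.train_ids) - 2
        # never worse than the restart's seed model
        assert scores[-1] >= scores[0]

    def test_reproducible_for_fixed_seed(self):
        cohort, split = _search_problem(seed=14)
        cfg = SearchConfig(restarts=8, seed=4)
        m1, t1 = run_search(cohort.matrix.columns, cohort.matrix, split, REGRESSION, cfg)
        m2, t2 = run_search(cohort.matrix.columns, cohort.matrix, split, REGRESSION, cfg)
        assert m1 == m2
        assert [s.mean_score for s in t1.steps] == [s.mean_score for s in t2.steps]

    def test_attains_exhaustive_best_on_small_pool(self):
        """With a handful of candidates and enough restarts the randomized
        search reaches the best subset found by full enumeration."""
        cohort, split = _search_problem(seed=15, n_cols=6)
        matrix = cohort.matrix
        candidates = matrix.columns[:4]
        Xtr = matrix.data.loc[split.train_ids, candidates].to_numpy()
        Xv = matrix.data.loc[split.val_ids, candidates].to_numpy()
        ytr = matrix.bmi.loc[split.train_ids].to_numpy()
        yv = matrix.bmi.loc[split.val_ids].to_numpy()
        best = -np.inf
        for r in range(1, 5):
            for subset in itertools.combinations(range(4), r):
                A = np.column_stack([Xtr[:, subset], np.ones(len(Xtr))])
                sol, *_ = np.linalg.lstsq(A, ytr, rcond=None)
                ptr = A @ sol
                pv = np.column_stack([Xv[:, subset], np.ones(len(Xv))]) @ sol
                score = (np.corrcoef(ytr, ptr)[0, 1] + np.corrcoef(yv, pv)[0, 1]) / 2
                best = max(best, score)
        model, trace = run_search(candidates, matrix, split, REGRESSION,
                                  SearchConfig(restarts=50, seed=5,
                                               exhaustive_subsets=True))
        assert trace.steps[-1].mean_score <= best + 1e-9
        assert trace.steps[-1].mean_score == pytest.approx(best, abs=1e-9)

    def test_classification_task_runs_and_scores_in_unit_interval(self):
        cohort, split = _search_problem(seed=16)
        model, trace = run_search(cohort.matrix.columns, cohort.matrix, split,
                                  CLASSIFICATION, SearchConfig(restarts=5, seed=6))
        last = trace.steps[-1]
        assert 0.0 <= last.train_score <= 1.0 and 0.0 <= last.val_score <= 1.0
        labels = group_labels(cohort.matrix, split.train_ids)
        assert set(labels) <= {-1, 1}

    def test_empty_candidates_rejected(self, small_cohort):
        split = stratified_split(small_cohort.subjects, (20, 10, 10), seed=0)
        with pytest.raises(ValueError, match="empty"):
            run_search([], small_cohort.matrix, split, REGRESSION)
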