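"""Balancing, hold-out, regression models and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

import gaitwomac as gw
from gaitwomac.errors import UndefinedStatisticError, ValidationError
from gaitwomac.estimation import (
    balance_downsample,
    evaluate,
    fit_linear,
    fit_random_forest,
    greedy_balanced_sizes,
    holdout_split,
    predict_linear,
)


def toy_population(n_mild=140, n_moderate=182, n_severe=53):
    ids = [f"s{i}" for i in range(n_mild + n_moderate + n_severe)]
    classes = ["mild"] * n_mild + ["moderate"] * n_moderate + ["severe"] * n_severe
    return ids, classes


class TestBalancing:
    def test_greedy_trimming_arithmetic(self):
        sizes = greedy_balanced_sizes({"mild": 140, "moderate": 182, "severe": 53}, 231)
        assert sizes == {"mild": 89, "moderate": 89, "severe": 53}

    def test_downsample_matches_target_sizes(self):
        ids, classes = toy_population()
        kept = balance_downsample(ids, classes, 231, seed=3)
        assert len(kept) == 231
        kept_classes = pd.Series(classes, index=ids).loc[kept]
        assert kept_classes.value_counts().to_dict() == {"mild": 89, "moderate": 89, "severe": 53}

    def test_identity_when_target_equals_cohort(self):
        ids, classes = toy_population(5, 6, 7)
        assert balance_downsample(ids, classes, 18, seed=0) == ids

    def test_deterministic_given_seed(self):
        ids, classes = toy_population()
        assert balance_downsample(ids, classes, 231, seed=9) == balance_downsample(
            ids, classes, 231, seed=9
        )

    def test_target_too_small_rejected(self):
        ids, classes = toy_population(3, 3, 3)
        with pytest.raises(ValidationError):
            balance_downsample(ids, classes, 2, seed=0)


class TestHoldout:
    def test_seventy_thirty_rounding(self):
        ids, classes = toy_population(89, 89, 53)
        train, test = holdout_split(ids, classes, 0.70, seed=1)
        assert (len(train), len(test)) == (162, 69)

    def test_half_split_of_ten(self):
        ids = [f"s{i}" for i in range(10)]
        train, test = holdout_split(ids, None, 0.5, seed=2, stratify=False)
        assert (len(train), len(test)) == (5, 5)

    def test_partition_properties(self):
        ids, classes = toy_population(30, 40, 20)
        train, test = holdout_split(ids, classes, 0.7, seed=5)
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_stratification_keeps_all_classes_on_both_sides(self):
        ids, classes = toy_population(20, 20, 10)
        train, test = holdout_split(ids, classes, 0.7, seed=8)
        lookup = pd.Series(classes, index=ids)
        assert set(lookup.loc[train].unique()) == {"mild", "moderate", "severe"}
        assert set(lookup.loc[test].unique()) == {"mild", "moderate", "severe"}


class TestEvaluate:
    def test_perfect_predictions(self):
        rmse, r = evaluate([1, 2, 3, 4], [1, 2, 3, 4])
        assert rmse == 0.0 and r == pytest.approx(1.0)

    def test_constant_shift(self):
        rmse, r = evaluate(np.array([1, 2, 3, 4]) + 5.0, [1, 2, 3, 4])
        assert rmse == pytest.approx(5.0) and r == pytest.approx(1.0)

    def test_hand_computed_oracle(self):
        rmse, r = evaluate([0, 10, 26], [0, 10, 20])
        assert rmse == pytest.approx(np.sqrt(12.0))
        assert r == pytest.approx(0.991241, abs=1e-6)

    def test_constant_actuals_undefined_correlation(self):
        with pytest.raises(UndefinedStatisticError):
            evaluate([1, 2, 3], [5, 5, 5])


class TestLinearModel:
    def test_exact_recovery_without_noise(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = 2.0 * X["a"] - 1.5 * X["b"] + 4.0
        coefs, intercept = fit_linear(X, y)
        assert coefs["a"] == pytest.approx(2.0, abs=1e-8)
        assert coefs["b"] == pytest.approx(-1.5, abs=1e-8)
        assert intercept == pytest.approx(4.0, abs=1e-8)
        rmse, _ = evaluate(predict_linear(X, coefs, intercept), y)
        assert rmse < 1e-8

    def test_noisy_slope_and_holdout_correlation(self, rng):
        n = 200
        x1 = rng.normal(size=n)
        y = 3.0 * x1 + rng.normal(size=n)
        X = pd.DataFrame({"x1": x1})
        coefs, intercept = fit_linear(X.iloc[:140], y[:140])
        assert coefs["x1"] == pytest.approx(3.0, abs=0.3)
        _, r = evaluate(predict_linear(X.iloc[140:], coefs, intercept), y[140:])
        # analytic attainable correlation sqrt(R^2) = 3/sqrt(10)
        assert r == pytest.approx(3 / np.sqrt(10), abs=0.08)

    def test_permuted_response_gives_null_correlation(self, rng):
        n = 120
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = 3 * X["x1"].to_numpy() + rng.normal(size=n)
        rs = []
        for _ in range(100):
            yp = rng.permutation(y)
            coefs, b0 = fit_linear(X.iloc[:80], yp[:80])
            _, r = evaluate(predict_linear(X.iloc[80:], coefs, b0), yp[80:])
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_collinear_design_fails_loudly_naming_columns(self, rng):
        x = rng.normal(size=40)
        X = pd.DataFrame({"a": x, "twice_a": 2 * x, "b": rng.normal(size=40)})
        with pytest.raises(ValidationError, match="collinear"):
            fit_linear(X, rng.normal(size=40))
        coefs, _ = fit_linear(X, rng.normal(size=40), on_collinear="pinv")
        assert set(coefs.index) == {"a", "twice_a", "b"}

    def test_more_features_than_subjects_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 8)))
        X.columns = [f"f{i}" for i in range(8)]
        with pytest.raises(ValidationError):
            fit_linear(X, rng.normal(size=5))


class TestRandomForest:
    def test_constant_response_reproduced(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        model = fit_random_forest(X, np.full(30, 42.0), seed=0)
        pred = model.predict(X.values)
        np.testing.assert_allclose(pred, 42.0)

    def test_learns_step_structure(self, rng):
        n = 300
        x1 = rng.uniform(-1, 1, n)
        y = np.where(x1 > 0, 10.0, 0.0) + rng.normal(0, 0.5, n)
        X = pd.DataFrame({"x1": x1})
        model = fit_random_forest(X.iloc[:200], y[:200], seed=1)
        rmse, _ = evaluate(model.predict(X.iloc[200:].values), y[200:])
        assert rmse < np.std(y)

    def test_seeded_reproducibility(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = rng.normal(size=60)
        p1 = fit_random_forest(X, y, seed=5).predict(X.values)
        p2 = fit_random_forest(X, y, seed=5).predict(X.values)
        np.testing.assert_array_equal(p1, p2)
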