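"""ANOVA screen, pairwise t gates, key-feature selection, subscales."""

import numpy as np
import pandas as pd
import pytest

import gaitwomac as gw
from gaitwomac.errors import ValidationError
from gaitwomac.extract import extract_matrix
from gaitwomac.selection import (
    anova_screen,
    pairwise_ttests,
    run_selection,
    select_key_features,
    subscale_association,
)


def frame(cols):
    X = pd.DataFrame(cols)
    X.index = [f"s{i}" for i in range(len(X))]
    return X


class TestAnovaScreen:
    def test_hand_computed_sums_of_squares(self):
        X = frame({"f": [1, 2, 3, 2, 3, 4, 3, 4, 5]})
        classes = ["mild"] * 3 + ["moderate"] * 3 + ["severe"] * 3
        out = anova_screen(X, classes, alpha=0.05)
        assert out.loc["f", "F"] == pytest.approx(3.0)
        assert not out.loc["f", "passed_anova"]  # p ~ 0.125 on (2, 6) df

    def test_identical_groups_give_zero_F(self):
        X = frame({"f": [1, 2, 3] * 3})
        classes = ["mild"] * 3 + ["moderate"] * 3 + ["severe"] * 3
        out = anova_screen(X, classes, alpha=0.0001)
        assert out.loc["f", "F"] == pytest.approx(0.0)
        assert not out.loc["f", "passed_anova"]

    def test_requires_three_populated_classes(self):
        X = frame({"f": [1, 2, 3, 4]})
        with pytest.raises(ValidationError):
            anova_screen(X, ["mild", "mild", "moderate", "moderate"])
        with pytest.raises(ValidationError):
            anova_screen(X, ["mild", "mild", "moderate", "severe"])

    def test_two_group_F_equals_squared_t(self, rng):
        """k = 2 consistency: drop one class and compare with the pooled t."""
        from scipy import stats

        a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)
        F, _ = stats.f_oneway(a, b)
        t, _ = stats.ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-10)


class TestPairwiseTTests:
    def test_pooled_t_oracle(self):
        X = frame({"f": [1, 2, 3, 4, 5, 6, 0, 5, 10]})
        classes = ["mild"] * 3 + ["moderate"] * 3 + ["severe"] * 3
        out = pairwise_ttests(X, classes, alpha=0.05)
        # mild {1,2,3} vs moderate {4,5,6}: t = -3.674, p = 0.0213 on 4 df
        assert out.loc["f", "p_mild_moderate"] == pytest.approx(0.021312, abs=1e-5)

    def test_identical_groups_not_passed(self):
        X = frame({"f": [1, 2, 3] * 3})
        classes = ["mild"] * 3 + ["moderate"] * 3 + ["severe"] * 3
        out = pairwise_ttests(X, classes, alpha=0.05)
        assert out.loc["f", "p_mild_moderate"] == pytest.approx(1.0)
        assert not out.loc["f", "passed_all_pairs"]

    def test_separated_normals_pass(self, rng):
        X = frame({"f": np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50),
                                        rng.normal(10, 1, 50)])})
        classes = ["mild"] * 50 + ["moderate"] * 50 + ["severe"] * 50
        out = pairwise_ttests(X, classes, alpha=0.00003)
        assert out.loc["f", "p_mild_moderate"] < 1e-10
        assert out.loc["f", "passed_all_pairs"]

    def test_zero_pooled_variance_is_undefined_not_passed(self):
        X = frame({"f": [1.0] * 9})
        classes = ["mild"] * 3 + ["moderate"] * 3 + ["severe"] * 3
        out = pairwise_ttests(X, classes)
        assert np.isnan(out.loc["f", "p_mild_moderate"])
        assert not out.loc["f", "passed_all_pairs"]


class TestKeyFeatureSelection:
    def test_empty_when_nothing_passes(self, rng):
        X = frame({f"f{i}": rng.normal(size=30) for i in range(5)})
        classes = ["mild"] * 10 + ["moderate"] * 10 + ["severe"] * 10
        res = run_selection(X, classes)
        assert select_key_features(res) == []

    def test_key_features_ordered_by_anova_p(self, rng):
        n = 60
        classes = ["mild"] * 20 + ["moderate"] * 20 + ["severe"] * 20
        shift = np.repeat([0.0, 1.0, 2.0], 20)
        X = frame({
            "weak": shift * 3 + rng.normal(size=n),
            "strong": shift * 8 + rng.normal(size=n),
        })
        res = run_selection(X, classes)
        keys = select_key_features(res)
        assert keys == ["strong", "weak"]
        assert res.table["key_feature"].sum() == 2

    def test_pairwise_only_computed_for_anova_passers(self, rng):
        n = 60
        classes = ["mild"] * 20 + ["moderate"] * 20 + ["severe"] * 20
        shift = np.repeat([0.0, 1.0, 2.0], 20)
        X = frame({"null": rng.normal(size=n), "sig": shift * 8 + rng.normal(size=n)})
        res = run_selection(X, classes)
        assert np.isnan(res.table.loc["null", "p_mild_moderate"])
        assert np.isfinite(res.table.loc["sig", "p_mild_moderate"])

    def test_lowering_alpha_never_enlarges_selection(self, feature_frame, cohort_labels):
        classes, _ = cohort_labels
        loose = run_selection(feature_frame, classes, alpha_anova=1e-3, alpha_pairwise=1e-4)
        strict = run_selection(feature_frame, classes, alpha_anova=1e-5, alpha_pairwise=1e-6)
        assert set(strict.key_features) <= set(loose.key_features)

    def test_permutation_family_wise_calibration(self, feature_frame, cohort_labels, rng):
        """With permuted class labels the two-gate screen almost never
        admits a feature (>= 200 permutations)."""
        classes, _ = cohort_labels
        labels = classes.loc[feature_frame.index].to_numpy()
        nonempty = 0
        for _ in range(200):
            perm = rng.permutation(labels)
            res = run_selection(feature_frame, perm)
            nonempty += bool(res.key_features)
        assert nonempty <= 10  # expected non-empty rate ~ a few percent


@pytest.fixture(scope="module")
def selected(feature_frame, cohort_labels, cohort):
    classes, _ = cohort_labels
    res = run_selection(feature_frame, classes.loc[feature_frame.index])
    sub_classes = {
        s: pd.Series(
            {c.trial.subject_id: gw.classify_subscale(c.womac, s).label for c in cohort}
        ).loc[feature_frame.index]
        for s in ("pain", "stiffness", "physical_function")
    }
    return res, sub_classes


class TestSubscaleAssociation:
    def test_subscale_sets_are_subsets_of_key_features(self, feature_frame, selected):
        res, sub_classes = selected
        key = res.key_features
        sets = subscale_association(feature_frame, sub_classes, key)
        for s, feats in sets.items():
            assert set(feats) <= set(key)

    def test_physical_function_dominates(self, feature_frame, selected):
        """The 17-item physical-function subscale tracks the total most
        closely, so it should relate to at least as many features as the
        short subscales."""
        res, sub_classes = selected
        sets = subscale_association(feature_frame, sub_classes, res.key_features)
        assert len(sets["physical_function"]) >= len(sets["pain"])
        assert len(sets["physical_function"]) >= len(sets["stiffness"])
        assert len(sets["physical_function"]) > 0

    def test_decoupled_subscale_yields_empty_set(self):
        """When one subscale is generated independently of severity, its
        association set is (almost always) empty."""
        empty = 0
        for seed in range(8):
            cfg = gw.CohortConfig(seed=400 + seed, subscale_decoupled="stiffness")
            subs = gw.generate_cohort(cfg)
            fm = extract_matrix([s.trial for s in subs], gw.key_feature_registry())
            X = fm.drop_masked_features().to_frame()
            classes = pd.Series(
                {s.trial.subject_id: gw.classify_total(s.womac).label for s in subs}
            )
            res = run_selection(X, classes.loc[X.index])
            stiff = pd.Series(
                {s.trial.subject_id: gw.classify_subscale(s.womac, "stiffness").label
                 for s in subs}
            )
            sets = subscale_association(
                X, {"stiffness": stiff.loc[X.index]}, res.key_features
            )
            empty += not sets["stiffness"]
        assert empty >= 7
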