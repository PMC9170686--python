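"""Four-method feature selection: power, type-I control, intersection."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_rng_matrix
from petimeline.features import FeatureMatrix, TimePoint
from petimeline.selection import (SelectionConfig, adaptive_lasso_select,
                                  intersect_features, select_features,
                                  tree_importance_select, univariate_select,
                                  SelectionResult)

TP = TimePoint(15, "gestational_week", 37)


def _fm(X: pd.DataFrame, y, categories: dict) -> FeatureMatrix:
    meta = pd.DataFrame([{"feature": c, "category": categories[c]} for c in X.columns])
    return FeatureMatrix(timepoint=TP, X=X, y=pd.Series(np.asarray(y, bool),
                                                        index=X.index),
                         patient_ids=pd.Series(X.index, index=X.index), meta=meta)


def _sparse_sim(seed=0, n=4000, beta=np.log(3.0)):
    """Binary diagnosis features with one planted effect plus demographics."""
    rng = np.random.default_rng(seed)
    dx = rng.random((n, 5)) < 0.25
    age = rng.normal(30, 5, n)
    logit = -2.6 + beta * dx[:, 0] + 0.02 * (age - 30)
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    X = pd.DataFrame({"demo__age": age,
                      **{f"dx_gw__c{i}": dx[:, i] * 1.0 for i in range(5)},
                      "dx_gw__constant": 0.0})
    cats = {"demo__age": "demographics", "dx_gw__constant": "diagnosis",
            **{f"dx_gw__c{i}": "diagnosis" for i in range(5)}}
    return _fm(X, y, cats)


class TestAdaptiveLasso:
    def test_planted_diagnosis_effect_recovered(self):
        res = adaptive_lasso_select(_sparse_sim(seed=1), seed=1)
        assert "dx_gw__c0" in res.selected

    def test_noise_feature_rarely_selected(self):
        hits = sum("dx_gw__c3" in adaptive_lasso_select(_sparse_sim(seed=s),
                                                        seed=s).selected
                   for s in range(20))
        assert hits <= 2

    def test_zero_variance_never_selected(self):
        res = adaptive_lasso_select(_sparse_sim(seed=2), seed=2)
        assert "dx_gw__constant" not in res.selected

    def test_all_selected_have_small_p(self):
        res = adaptive_lasso_select(_sparse_sim(seed=3), seed=3)
        stats = res.statistics.set_index("feature")
        assert (stats.loc[res.selected, "p_value"] < 0.05).all()


def _dense_sim(seed=0, n=1200, beta=0.8, missing_feature=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    age = rng.normal(30, 5, n)
    logit = -2.3 + beta * x
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    X = pd.DataFrame({"demo__age": age, "vital__sbp__ante__max": x,
                      "lab__noise__ante__median": rng.normal(size=n)})
    if missing_feature:
        sparse = np.full(n, np.nan)
        sparse[:9] = rng.normal(size=9) + 5 * y[:9]   # 9 valid values only
        X["lab__rare__ante__max"] = sparse
    cats = {c: ("demographics" if c.startswith("demo") else
                "vital" if c.startswith("vital") else "lab") for c in X.columns}
    return _fm(X, y, cats)


class TestUnivariate:
    def test_planted_vital_effect_selected(self):
        res = univariate_select(_dense_sim(seed=1))
        assert "vital__sbp__ante__max" in res.selected

    def test_below_ten_valid_values_excluded(self):
        res = univariate_select(_dense_sim(seed=2, missing_feature=True))
        assert "lab__rare__ante__max" not in res.selected
        assert "lab__rare__ante__max" not in set(res.statistics.get("feature", []))

    def test_null_type_one_error_near_nominal(self):
        hits = 0
        for s in range(100):
            res = univariate_select(_dense_sim(seed=s, beta=0.0, n=400))
            hits += "lab__noise__ante__median" in res.selected
        assert hits / 100 < 0.12  # ~5% nominal


class TestTreeImportance:
    def test_quartile_rule_returns_top_quarter(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(400, 100)),
                         columns=[f"lab__f{i}__ante__max" for i in range(100)])
        y = (X.iloc[:, 0] + 0.5 * rng.normal(size=400)) > 0
        fm = _fm(X, y, {c: "lab" for c in X.columns})
        rf, xgb = tree_importance_select(fm, seed=0)
        # with continuous data importances are almost surely distinct
        assert len(rf.selected) == 25
        assert len(xgb.selected) == 25

    def test_informative_feature_ranks_in_both(self):
        X, y = make_rng_matrix(n=1500, p=12, informative=(0,), beta=1.5, seed=3)
        Xdf = pd.DataFrame(X, columns=[f"lab__f{i}__ante__max" for i in range(12)])
        fm = _fm(Xdf, y, {c: "lab" for c in Xdf.columns})
        rf, xgb = tree_importance_select(fm, seed=3)
        assert "lab__f0__ante__max" in rf.selected
        assert "lab__f0__ante__max" in xgb.selected

    def test_constant_feature_never_passes(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"lab__sig__ante__max": rng.normal(size=600),
                          **{f"dx_gw__z{i}": np.zeros(600) for i in range(5)}})
        y = X["lab__sig__ante__max"] + 0.3 * rng.normal(size=600) > 0
        cats = {c: ("lab" if "sig" in c else "diagnosis") for c in X.columns}
        rf, xgb = tree_importance_select(_fm(X, y, cats), seed=1)
        assert not any(f.startswith("dx_gw__z") for f in rf.selected + xgb.selected)


class TestIntersection:
    def _results(self, fm, lasso_sel, uni_sel, rf_sel, xgb_sel):
        empty = pd.DataFrame()
        return (SelectionResult("adaptive_lasso", lasso_sel, empty),
                SelectionResult("univariate", uni_sel, empty),
                SelectionResult("random_forest", rf_sel, empty),
                SelectionResult("xgboost", xgb_sel, empty))

    def test_set_algebra(self):
        X = pd.DataFrame(np.zeros((4, 3)), columns=["dx_gw__A", "dx_gw__B",
                                                    "lab__C__ante__max"])
        fm = _fm(X, [0, 1, 0, 1], {"dx_gw__A": "diagnosis", "dx_gw__B": "diagnosis",
                                   "lab__C__ante__max": "lab"})
        final = intersect_features(fm, *self._results(
            fm, ["dx_gw__A", "dx_gw__B"], ["lab__C__ante__max"],
            ["dx_gw__B", "lab__C__ante__max"], ["dx_gw__B", "lab__C__ante__max"]),
            fallback=False)
        assert final == ["dx_gw__B", "lab__C__ante__max"]

    def test_feature_failing_its_statistical_method_is_excluded(self):
        X = pd.DataFrame(np.zeros((4, 1)), columns=["lab__C__ante__max"])
        fm = _fm(X, [0, 1, 0, 1], {"lab__C__ante__max": "lab"})
        final = intersect_features(fm, *self._results(
            fm, [], [], ["lab__C__ante__max"], ["lab__C__ante__max"]),
            fallback=False)
        assert final == []

    def test_final_is_subset_of_every_method(self, mid_cohort):
        from petimeline import FeatureBuilder, build_timepoint_schedule

        ehr, journeys, labels = mid_cohort
        fm = FeatureBuilder(ehr, journeys, labels).matrix(
            build_timepoint_schedule()[14])
        bundle = select_features(fm, seed=0)
        cats = fm.categories()
        trees = (set(bundle.per_method["random_forest"].selected)
                 & set(bundle.per_method["xgboost"].selected))
        if bundle.intersection_size:
            for f in bundle.final:
                assert f in trees
                if cats[f] in ("vital", "lab"):
                    assert f in bundle.per_method["univariate"].selected
                else:
                    assert f in bundle.per_method["adaptive_lasso"].selected

    def test_selection_deterministic_given_seed(self, mid_cohort):
        from petimeline import FeatureBuilder, build_timepoint_schedule

        ehr, journeys, labels = mid_cohort
        fm = FeatureBuilder(ehr, journeys, labels).matrix(
            build_timepoint_schedule()[10])
        a = select_features(fm, seed=5)
        b = select_features(fm, seed=5)
        assert a.final == b.final
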