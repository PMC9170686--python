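"""Attributions, relative-risk transform, curves, odds ratios, networks."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import lightgbm as lgb
import networkx as nx

from petimeline import (FeatureBuilder, build_timepoint_schedule, select_features,
                        TimepointModel)
from petimeline.explain import (ShapExplanation, adjusted_odds_ratio, compute_shap,
                                export_network, feature_sweep_reduce,
                                group_contribution, moving_average_curve,
                                rr_transform)


@pytest.fixture(scope="module")
def fitted(mid_cohort):
    """Week-37 model + matrix fitted once for all attribution tests."""
    ehr, journeys, labels = mid_cohort
    fm = FeatureBuilder(ehr, journeys, labels).matrix(build_timepoint_schedule()[14])
    bundle = select_features(fm, seed=0)
    res = TimepointModel.from_feature_matrix(fm, features=bundle.final).fit(
        k=5, seed=0)
    return fm, res


class TestShap:
    def test_additivity_holds_for_every_sample(self, fitted):
        fm, res = fitted
        expl = compute_shap(res.models[0], fm.X[res.features])
        assert expl.additivity_gap().max() < 1e-6

    def test_single_stump_puts_all_mass_on_split_feature(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        y = (X["a"] > 0).astype(int)
        clf = lgb.LGBMClassifier(n_estimators=1, num_leaves=2, min_child_samples=5,
                                 learning_rate=1.0, verbose=-1).fit(X, y)
        expl = compute_shap(clf, X)
        assert np.allclose(expl.values["b"], 0.0)
        assert np.abs(expl.values["a"]).max() > 0

    def test_duplicated_rows_share_attributions(self, fitted):
        fm, res = fitted
        X2 = pd.concat([fm.X.iloc[:1], fm.X.iloc[:1]])[res.features]
        expl = compute_shap(res.models[0], X2)
        assert np.allclose(expl.values.iloc[0], expl.values.iloc[1])

    def test_non_tree_model_rejected(self):
        with pytest.raises(TypeError):
            compute_shap(object(), pd.DataFrame({"a": [1.0]}))


class TestRelativeRisk:
    def _expl(self, phi0, phis):
        vals = pd.DataFrame({"f": phis})
        return ShapExplanation(values=vals, base_value=phi0,
                               raw_output=phi0 + vals.sum(axis=1).to_numpy())

    def test_zero_attribution_is_exactly_one(self):
        assert rr_transform(self._expl(-2.0, [0.0]), "f")[0] == 1.0

    def test_numeric_identity_at_population_base(self):
        # phi0 = logit(0.093), phi = 0.5
        rr = rr_transform(self._expl(float(logit(0.093)), [0.5]), "f")[0]
        expected = expit(logit(0.093) + 0.5) / 0.093
        assert rr == pytest.approx(expected)
        assert rr == pytest.approx(1.555, abs=5e-3)

    def test_monotone_in_attribution(self):
        phis = np.linspace(-3, 3, 25)
        rr = rr_transform(self._expl(-2.0, phis), "f")
        assert (np.diff(rr) > 0).all()

    def test_full_subset_reproduces_prediction_ratio(self, fitted):
        fm, res = fitted
        X = fm.X[res.features].iloc[:50]
        expl = compute_shap(res.models[0], X)
        rr = rr_transform(expl, list(X.columns))
        pred = res.models[0].predict_proba(X.astype(float))[:, 1]
        assert np.allclose(rr, pred / expit(expl.base_value), atol=1e-6)

    def test_bounded_by_inverse_base_rate(self):
        phis = np.linspace(-5, 10, 50)
        rr = rr_transform(self._expl(-2.0, phis), "f")
        assert (rr > 0).all() and (rr < 1 / expit(-2.0)).all()


class TestGroupContribution:
    def test_shares_sum_to_hundred_and_order_invariant(self, fitted):
        fm, res = fitted
        expl = compute_shap(res.models[0], fm.X[res.features])
        cats = {f: fm.categories()[f] for f in res.features}
        shares = group_contribution(expl, cats)
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)
        shuffled = ShapExplanation(values=expl.values[expl.values.columns[::-1]],
                                   base_value=expl.base_value,
                                   raw_output=expl.raw_output)
        pd.testing.assert_series_equal(shares.sort_index(),
                                       group_contribution(shuffled, cats).sort_index())

    def test_all_attribution_in_one_category(self):
        vals = pd.DataFrame({"a": [1.0, -1.0], "b": [0.0, 0.0]})
        expl = ShapExplanation(vals, 0.0, vals.sum(axis=1).to_numpy())
        shares = group_contribution(expl, {"a": "vital", "b": "lab"})
        assert shares["vital"] == pytest.approx(100.0)

    def test_equal_categories_split_evenly(self):
        vals = pd.DataFrame({"a": [1.0, -1.0], "b": [-1.0, 1.0]})
        expl = ShapExplanation(vals, 0.0, vals.sum(axis=1).to_numpy())
        shares = group_contribution(expl, {"a": "vital", "b": "lab"})
        assert shares["vital"] == pytest.approx(50.0)

    def test_unmapped_feature_is_an_error(self):
        vals = pd.DataFrame({"a": [1.0]})
        expl = ShapExplanation(vals, 0.0, np.array([1.0]))
        with pytest.raises(KeyError, match="a"):
            group_contribution(expl, {})


class TestMovingAverage:
    def test_constant_signal_flat_curve(self):
        obs = pd.DataFrame({"day": np.repeat(np.arange(0, 100), 2),
                            "value": 120.0, "group": "pe"})
        ma = moving_average_curve(obs)
        mid = ma[(ma["day"] > 20) & (ma["day"] < 80)]
        assert np.allclose(mid["mean"], 120.0)
        assert np.allclose(mid["sd"], 0.0)

    def test_step_transitions_across_window(self):
        days = np.arange(0, 280)
        obs = pd.DataFrame({"day": days, "value": np.where(days < 140, 100.0, 110.0),
                            "group": "pe"})
        ma = moving_average_curve(obs, window_days=28)
        assert np.allclose(ma.loc[ma["day"] == 100, "mean"], 100.0)
        assert np.allclose(ma.loc[ma["day"] == 180, "mean"], 110.0)
        at_step = float(ma.loc[ma["day"] == 140, "mean"].iloc[0])
        assert 100.0 < at_step < 110.0
        # direct windowed mean as the oracle at one day
        d = 150
        lo, hi = d - 14, d + 14
        oracle = obs[(obs["day"] >= lo) & (obs["day"] < hi)]["value"].mean()
        got = float(ma.loc[ma["day"] == d, "mean"].iloc[0])
        assert got == pytest.approx(oracle, abs=0.5)

    def test_gap_days_are_nan(self):
        obs = pd.DataFrame({"day": [0, 1, 2, 200], "value": 1.0, "group": "g"})
        ma = moving_average_curve(obs)
        assert np.isnan(ma.loc[ma["day"] == 100, "mean"]).all()

    def test_planted_case_offset_visible_post_onset(self, mid_cohort):
        ehr, journeys, labels = mid_cohort
        fb = FeatureBuilder(ehr, journeys, labels)
        vit = fb.vitals[(fb.vitals["type"] == "sbp") & (fb.vitals["period"] == "ante")
                        & (fb.vitals["day"] > 0) & (fb.vitals["value"] < 300)]
        is_pe = labels.set_index("journey_id")["is_pe"]
        obs = vit.assign(group=np.where(is_pe.loc[vit["journey_id"]], "pe", "control"),
                         value=vit["value"])
        ma = moving_average_curve(obs[["day", "value", "group"]])
        late = ma[(ma["day"] >= 240) & (ma["day"] <= 270)].pivot_table(
            index="day", columns="group", values="mean")
        sep = (late["pe"] - late["control"]).mean()
        assert sep > 3.0  # elevated yet in-range systolic pressure in cases


class TestAdjustedOddsRatio:
    def test_null_feature_ci_covers_one(self):
        covers = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            n = 800
            x = pd.Series(rng.normal(size=n))
            y = rng.random(n) < 0.15
            cov = pd.DataFrame({"age": rng.normal(30, 5, n)})
            fa = adjusted_odds_ratio(x, y, cov)
            covers += fa.ci_low <= 1.0 <= fa.ci_high
        assert covers >= 90

    def test_planted_effect_recovered(self):
        # nominal 95% CI: require >=90% empirical coverage of the planted OR
        n_reps = 300
        covers = 0
        for s in range(n_reps):
            rng = np.random.default_rng(1000 + s)
            n = 5000
            x = rng.normal(size=n)
            lo = -2.5 + np.log(2.0) * x
            y = rng.random(n) < expit(lo)
            fa = adjusted_odds_ratio(pd.Series(x), y,
                                     pd.DataFrame({"age": rng.normal(size=n)}))
            covers += fa.ci_low <= 2.0 <= fa.ci_high
        assert covers >= 0.9 * n_reps

    def test_constant_feature_flagged(self):
        with pytest.raises(ValueError):
            adjusted_odds_ratio(pd.Series(np.ones(100)), np.zeros(100),
                                pd.DataFrame({"age": np.zeros(100)}))

    def test_direction_follows_odds_ratio(self):
        rng = np.random.default_rng(3)
        n = 3000
        x = rng.normal(size=n)
        y = rng.random(n) < expit(-2 - 1.0 * x)
        fa = adjusted_odds_ratio(pd.Series(x), y,
                                 pd.DataFrame({"age": rng.normal(size=n)}))
        assert fa.odds_ratio < 1 and fa.direction == "protective"


class TestFeatureSweep:
    def test_flat_sequence_returns_single_feature(self):
        feats = [f"f{i}" for i in range(8)]
        sel, _ = feature_sweep_reduce(feats, lambda p: 0.8)
        assert sel == ["f0"]

    def test_rise_then_plateau_returns_knee(self):
        aucs = {1: 0.70, 2: 0.75, 3: 0.80, 4: 0.85, 5: 0.90,
                6: 0.9005, 7: 0.9008, 8: 0.9010, 9: 0.9011}
        feats = [f"f{i}" for i in range(9)]
        sel, _ = feature_sweep_reduce(feats, lambda p: aucs[len(p)])
        assert len(sel) == 5

    def test_infinite_tolerance_returns_one(self):
        feats = [f"f{i}" for i in range(6)]
        sel, _ = feature_sweep_reduce(feats, lambda p: 0.6 + 0.05 * len(p),
                                      tol=np.inf)
        assert sel == ["f0"]


class TestNetwork:
    def _assoc(self):
        return pd.DataFrame({
            "timepoint": ["week_37", "week_38", "week_38"],
            "feature": ["f1", "f1", "lonely"],
            "odds_ratio": [2.0, 0.5, 1.2],
            "p_value": [0.01, 0.02, 0.04],
            "importance": [0.5, 0.4, 0.1]})

    def test_node_and_edge_counts(self):
        g = export_network(self._assoc().iloc[:2])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_protective_edges_colored_blue(self):
        g = export_network(self._assoc())
        assert g.edges["PE@week_38", "f1"]["color"] == "blue"
        assert g.edges["PE@week_37", "f1"]["color"] == "red"

    def test_antepartum_scope_drops_single_timepoint_features(self):
        g = export_network(self._assoc(), scope="antepartum")
        assert "lonely" not in g.nodes

    def test_graphml_round_trip(self, tmp_path):
        path = tmp_path / "net.graphml"
        g = export_network(self._assoc(), path=path)
        g2 = nx.read_graphml(path)
        assert set(g2.nodes) == set(g.nodes)
        assert g2.edges["PE@week_37", "f1"]["odds_ratio"] == 2.0

    def test_empty_associations_warn(self):
        with pytest.warns(UserWarning):
            g = export_network(pd.DataFrame(columns=["timepoint", "feature",
                                                     "odds_ratio", "importance"]))
        assert g.number_of_nodes() == 0
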