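"""Model interpretation: TreeSHAP attributions, the relative-risk
transform, category contributions, moving-average curves, adjusted odds
ratios, SHAP-rank feature reduction, and network export.

Attributions are additive in log-odds: for every sample,
``f(x) = phi0 + sum_i phi_i`` where ``f(x)`` is the model's raw (log-odds)
output and ``phi0`` the expected output.  A single feature's attribution
maps to a relative risk against the population baseline via

    RR_i = sigmoid(phi0 + phi_i) / sigmoid(phi0)

and a grouped attribution replaces ``phi_i`` with the sum over the group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lightgbm as lgb
import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit


@dataclass
class ShapExplanation:
    """Per-sample additive attributions (log-odds) with base value phi0."""

    values: pd.DataFrame          # samples x features
    base_value: float             # phi0, log-odds of the expected output
    raw_output: np.ndarray        # f(x), log-odds, for the additivity check

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def additivity_gap(self) -> np.ndarray:
        """|phi0 + sum_i phi_i - f(x)| per sample (exact TreeSHAP: ~0)."""
        return np.abs(self.base_value + self.values.sum(axis=1).to_numpy()
                      - self.raw_output)

    def mean_abs(self) -> pd.Series:
        """Global importance: mean |phi| per feature, descending."""
        return self.values.abs().mean(axis=0).sort_values(ascending=False)


def compute_shap(model, X: pd.DataFrame) -> ShapExplanation:
    """Exact tree-path attributions for a fitted boosted-tree model."""
    if isinstance(model, lgb.LGBMClassifier):
        booster = model.booster_
    elif isinstance(model, lgb.Booster):
        booster = model
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}; "
                        "tree-structured LightGBM models only")
    Xv = X.to_numpy(float)
    contrib = booster.predict(Xv, pred_contrib=True)
    raw = booster.predict(Xv, raw_score=True)
    phi = pd.DataFrame(contrib[:, :-1], index=X.index, columns=list(X.columns))
    base = float(contrib[0, -1])
    return ShapExplanation(values=phi, base_value=base, raw_output=np.asarray(raw))


def rr_transform(explanation: ShapExplanation, features) -> np.ndarray:
    """Relative risk of one feature (or a feature subset, whose phi are
    summed) against the population baseline sigmoid(phi0)."""
    if isinstance(features, str):
        phi = explanation.values[features].to_numpy()
    else:
        phi = explanation.values[list(features)].sum(axis=1).to_numpy()
    phi0 = explanation.base_value
    return expit(phi0 + phi) / expit(phi0)


def group_contribution(explanation: ShapExplanation,
                       category_map: dict[str, str]) -> pd.Series:
    """Per-category share of predictive power: mean |phi| over the
    category's features and all samples, normalized to sum to 100%."""
    unmapped = [f for f in explanation.values.columns if f not in category_map]
    if unmapped:
        raise KeyError(f"features missing from category map: {unmapped}")
    absmean = explanation.values.abs().mean(axis=0)
    cats = pd.Series({f: category_map[f] for f in absmean.index})
    per_cat = absmean.groupby(cats).mean()
    return (per_cat / per_cat.sum() * 100.0).sort_values(ascending=False)


def moving_average_curve(obs: pd.DataFrame, window_days: int = 28,
                         day_col: str = "day", value_col: str = "value",
                         group_col: str = "group") -> pd.DataFrame:
    """Centered moving average (and SD) per group on a daily grid.

    ``obs`` carries gestational-day offsets; days whose window contains no
    observation are gaps (NaN).
    """
    frames = []
    d0 = int(np.floor(obs[day_col].min()))
    d1 = int(np.ceil(obs[day_col].max()))
    grid = np.arange(d0, d1 + 1)
    for grp, sub in obs.groupby(group_col):
        day = np.floor(sub[day_col]).astype(int)
        agg = pd.DataFrame({
            "n": sub.groupby(day)[value_col].size(),
            "s": sub.groupby(day)[value_col].sum(),
            "ss": sub.groupby(day)[value_col].apply(lambda v: np.sum(v ** 2)),
        }).reindex(grid, fill_value=0.0)
        roll = agg.rolling(window=window_days, center=True, min_periods=1).sum()
        n = roll["n"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, roll["s"] / n, np.nan)
            var = np.where(n > 1, roll["ss"] / n - mean ** 2, np.nan)
        frames.append(pd.DataFrame({
            "day": grid, "group": grp, "mean": mean,
            "sd": np.sqrt(np.clip(var, 0.0, None)), "n": n.astype(int)}))
    return pd.concat(frames, ignore_index=True)


@dataclass
class FeatureAssociation:
    """Adjusted odds ratio of one feature with its 95% CI and importance."""

    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    importance: float = float("nan")
    flagged: bool = False

    @property
    def direction(self) -> str:
        return "risk" if self.odds_ratio > 1 else "protective"


def adjusted_odds_ratio(x: pd.Series, y, covariates: pd.DataFrame,
                        feature_name: str | None = None,
                        importance: float = float("nan")) -> FeatureAssociation:
    """OR per SD of the feature from a logistic fit adjusted for the
    demographic covariates (complete cases)."""
    name = feature_name or (x.name if x.name else "feature")
    valid = x.notna()
    xv = x[valid]
    if xv.std(ddof=0) == 0 or valid.sum() < 10:
        raise ValueError(f"feature {name!r} is constant or too sparse for an OR")
    z = (xv - xv.mean()) / xv.std()
    D = covariates.loc[valid].fillna(0.0).copy()
    D["_feat"] = z
    D = sm.add_constant(D, has_constant="add")
    yv = np.asarray(pd.Series(y)[valid], int)
    flagged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(yv, D).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.bse["_feat"]):
            raise np.linalg.LinAlgError("separation")
        beta, se, p = fit.params["_feat"], fit.bse["_feat"], fit.pvalues["_feat"]
    except Exception:  # separation -> penalized fallback, flagged
        flagged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(yv, D).fit_regularized(disp=0, alpha=1.0, maxiter=200)
        beta = float(fit.params["_feat"])
        cov = np.linalg.pinv(D.T.values @ D.values)
        se = float(np.sqrt(max(cov[list(D.columns).index("_feat"),
                                   list(D.columns).index("_feat")], 1e-12)))
        from scipy import stats as sps
        p = float(2 * sps.norm.sf(abs(beta / se)))
    return FeatureAssociation(
        feature=name, odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)), ci_high=float(np.exp(beta + 1.96 * se)),
        p_value=float(p), importance=importance, flagged=flagged)


def feature_sweep_reduce(ranked_features: list[str], evaluate,
                         tol: float = 0.002, patience: int = 3):
    """Shortest SHAP-ranked prefix after which performance is flat.

    ``evaluate(prefix)`` returns the AUC of a model restricted to the
    prefix.  Flatness = ``patience`` consecutive additions each gaining
    less than ``tol`` AUC.  Returns (selected prefix, AUC sequence).
    """
    aucs = [float(evaluate(ranked_features[:1]))]
    streak = 0
    for k in range(2, len(ranked_features) + 1):
        aucs.append(float(evaluate(ranked_features[:k])))
        gain = aucs[-1] - aucs[-2]
        streak = streak + 1 if gain < tol else 0
        if streak >= patience:
            return ranked_features[:k - patience], aucs
    m = max(1, len(aucs) - streak)
    return ranked_features[:m], aucs


def export_network(associations: pd.DataFrame, scope: str = "period",
                   path=None) -> nx.Graph:
    """Bipartite time-point / feature association network.

    ``associations`` columns: timepoint, feature, odds_ratio, p_value,
    importance.  Square nodes are case time points or periods; round nodes
    are features sized by importance.  Edge color encodes direction
    (red OR > 1, blue OR < 1), width encodes importance.  In the
    per-antepartum-time-point scope, features predictive at only one time
    point are dropped.
    """
    assoc = associations.copy()
    g = nx.Graph()
    if assoc.empty:
        warnings.warn("empty association set; returning empty graph")
        return g
    if scope == "antepartum":
        counts = assoc.groupby("feature")["timepoint"].nunique()
        assoc = assoc[assoc["feature"].map(counts) > 1]
    for tp in assoc["timepoint"].unique():
        g.add_node(f"PE@{tp}", kind="timepoint", shape="square")
    imp = assoc.groupby("feature")["importance"].mean()
    for feat, v in imp.items():
        g.add_node(feat, kind="feature", shape="round", size=float(v))
    for _, r in assoc.iterrows():
        g.add_edge(f"PE@{r['timepoint']}", r["feature"],
                   odds_ratio=float(r["odds_ratio"]),
                   color="red" if r["odds_ratio"] > 1 else "blue",
                   width=float(r["importance"]),
                   p_value=float(r.get("p_value", float("nan"))))
    if path is not None:
        nx.write_graphml(g, path)
    return g
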