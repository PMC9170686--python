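"""Four-method feature selection with per-domain intersection.

Sparse event features (diagnoses, medications, procedures — absent events
encoded as zero) and demographics go through an adaptive-LASSO penalized
logistic regression; vital and lab features, whose missingness is
informative and cannot be zero-filled, go through demographics-adjusted
univariate logistic fits on complete cases.  All features additionally go
through a random forest and a gradient-boosted tree fitted on an 80%
bootstrap, each keeping features at or above its own 75th importance
percentile.  A feature survives only if every method that scored its
domain kept it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from xgboost import XGBClassifier

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

SPARSE_CATEGORIES = ("diagnosis", "medication", "procedure")
DENSE_CATEGORIES = ("vital", "lab")


@dataclass
class SelectionResult:
    method: str
    selected: list[str]
    statistics: pd.DataFrame      # per-feature coefficient / p-value / importance
    threshold: float | None = None


@dataclass
class SelectionConfig:
    p_threshold: float = 0.05
    min_valid_values: int = 10
    bootstrap_frac: float = 0.80
    importance_percentile: float = 75.0
    ridge_c: float = 1.0
    lasso_cs: int = 8
    lasso_cv: int = 5
    rf_estimators: int = 200
    xgb_estimators: int = 150
    adjust_demographics: tuple[str, ...] = (
        "demo__age", "demo__medicaid", "demo__race__African American",
        "demo__race__Caucasian", "demo__race__Asian", "demo__race__Hispanic")


def _zero_filled_sparse(fm: FeatureMatrix) -> pd.DataFrame:
    """Sparse-track sub-matrix: first-timing features with absent events as
    zero, plus demographics."""
    cats = fm.categories()
    sparse_cols = [c for c in fm.X.columns if cats.get(c) in SPARSE_CATEGORIES]
    demo_cols = [c for c in fm.X.columns if cats.get(c) == "demographics"]
    Xs = fm.X[sparse_cols].fillna(0.0)
    Xd = fm.X[demo_cols].fillna(0.0)
    return pd.concat([Xd, Xs], axis=1)


def adaptive_lasso_select(fm: FeatureMatrix, config: SelectionConfig | None = None,
                          seed: int = 0) -> SelectionResult:
    """Adaptive LASSO on the sparse track + demographics.

    Ridge coefficients set the adaptive weights (w_j = 1/|beta_ridge_j|),
    the L1 penalty is chosen by cross-validated deviance, and p-values come
    from an unpenalized refit on the selected support; keep p < 0.05.
    """
    config = config or SelectionConfig()
    X = _zero_filled_sparse(fm)
    y = fm.y.astype(int).to_numpy()
    keep_var = X.std(axis=0) > 0
    X = X.loc[:, keep_var]
    if X.shape[1] == 0 or y.sum() in (0, len(y)):
        return SelectionResult("adaptive_lasso", [], pd.DataFrame(), None)
    mu, sd = X.mean(), X.std().replace(0, 1.0)
    Z = (X - mu) / sd

    ridge = LogisticRegression(C=config.ridge_c, max_iter=2000)
    ridge.fit(Z, y)
    w = np.abs(ridge.coef_.ravel()) + 1e-8
    Zw = Z * w  # scaling columns by |beta_ridge| == penalizing by 1/|beta_ridge|

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # bounded penalty path: very weak penalties only thrash the solver
        # on near-separable minority-class data
        lasso = LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=np.logspace(-3, 1, config.lasso_cs),
            cv=config.lasso_cv, scoring="neg_log_loss", max_iter=300,
            random_state=seed)
        lasso.fit(Zw, y)
    support = np.flatnonzero(np.abs(lasso.coef_.ravel()) > 1e-10)
    cols = list(X.columns[support])
    stats_rows = []
    selected: list[str] = []
    if cols:
        design = sm.add_constant(Z[cols], has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            pvals = fit.pvalues
            coefs = fit.params
            if not np.all(np.isfinite(fit.bse)):
                raise np.linalg.LinAlgError("unstable refit")
        except Exception:  # complete separation: penalized refit fallback
            logger.warning("adaptive LASSO refit unstable; using penalized fallback")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit_regularized(disp=0, alpha=1.0, maxiter=200)
            coefs = fit.params
            se = np.sqrt(np.maximum(np.diag(
                np.linalg.pinv(design.T.values @ design.values)), 1e-12))
            from scipy import stats as sps
            pvals = pd.Series(
                2 * sps.norm.sf(np.abs(coefs.to_numpy() / se)), index=coefs.index)
        for c in cols:
            p = float(pvals.get(c, 1.0))
            stats_rows.append({"feature": c, "coef": float(coefs.get(c, 0.0)),
                               "p_value": p})
            if p < config.p_threshold:
                selected.append(c)
    return SelectionResult("adaptive_lasso", selected,
                           pd.DataFrame(stats_rows), config.p_threshold)


def univariate_select(fm: FeatureMatrix, config: SelectionConfig | None = None) -> SelectionResult:
    """Demographics-adjusted univariate logistic fits for vital/lab features.

    Each feature is fitted on complete cases and needs at least
    ``min_valid_values`` non-missing values; keep p < 0.05.
    """
    config = config or SelectionConfig()
    cats = fm.categories()
    cols = [c for c in fm.X.columns if cats.get(c) in DENSE_CATEGORIES]
    demo = [c for c in config.adjust_demographics if c in fm.X.columns]
    y_all = fm.y.astype(int)
    rows, selected = [], []
    for c in cols:
        x = fm.X[c]
        valid = x.notna()
        if int(valid.sum()) < config.min_valid_values:
            continue
        yv = y_all[valid]
        if yv.nunique() < 2 or x[valid].std() == 0:
            continue
        D = fm.X.loc[valid, demo].fillna(0.0).copy()
        D[c] = (x[valid] - x[valid].mean()) / (x[valid].std() or 1.0)
        D = sm.add_constant(D, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yv, D).fit(disp=0, maxiter=200)
            p = float(fit.pvalues[c])
            if not np.isfinite(p):
                raise ValueError("non-finite p")
        except Exception:
            logger.info("univariate fit failed for %s; skipped", c)
            continue
        rows.append({"feature": c, "coef": float(fit.params[c]), "p_value": p,
                     "n_valid": int(valid.sum())})
        if p < config.p_threshold:
            selected.append(c)
    return SelectionResult("univariate", selected, pd.DataFrame(rows), config.p_threshold)


def _importance_select(name: str, importances: np.ndarray, features: list[str],
                       percentile: float) -> SelectionResult:
    thr = float(np.percentile(importances, percentile))
    keep = [f for f, imp in zip(features, importances) if imp >= thr and imp > 0]
    stats = pd.DataFrame({"feature": features, "importance": importances})
    return SelectionResult(name, keep, stats, thr)


def tree_importance_select(fm: FeatureMatrix, config: SelectionConfig | None = None,
                           seed: int = 0) -> tuple[SelectionResult, SelectionResult]:
    """Random-forest and boosted-tree importances on an 80% bootstrap.

    Both learners route missing values natively; each keeps features with
    importance at or above its own 75th percentile (ties kept, zeros never
    kept).  A single-class bootstrap is redrawn with a new seed.
    """
    config = config or SelectionConfig()
    rng = np.random.default_rng(seed)
    X = fm.X.to_numpy(float)
    y = fm.y.astype(int).to_numpy()
    n = len(y)
    m = int(round(config.bootstrap_frac * n))
    for attempt in range(10):
        idx = rng.integers(0, n, size=m)
        if len(np.unique(y[idx])) > 1:
            break
        logger.warning("single-class bootstrap, resampling (attempt %d)", attempt + 1)
    Xb, yb = X[idx], y[idx]
    feats = list(fm.X.columns)

    rf = RandomForestClassifier(n_estimators=config.rf_estimators, n_jobs=1,
                                random_state=seed)
    rf.fit(Xb, yb)
    rf_res = _importance_select("random_forest", rf.feature_importances_, feats,
                                config.importance_percentile)

    xgb = XGBClassifier(n_estimators=config.xgb_estimators, max_depth=4,
                        learning_rate=0.1, n_jobs=1, random_state=seed,
                        verbosity=0, eval_metric="logloss")
    xgb.fit(Xb, yb)
    xgb_res = _importance_select("xgboost", xgb.feature_importances_, feats,
                                 config.importance_percentile)
    return rf_res, xgb_res


def intersect_features(fm: FeatureMatrix, lasso: SelectionResult,
                       univariate: SelectionResult, rf: SelectionResult,
                       xgb: SelectionResult, fallback: bool = True) -> list[str]:
    """Per-domain intersection: sparse-track and demographic features must
    pass LASSO and both tree methods; vital/lab features must pass the
    univariate fit and both tree methods.  Empty result falls back to
    demographics only (warned) unless ``fallback`` is off."""
    cats = fm.categories()
    trees = set(rf.selected) & set(xgb.selected)
    final = []
    for f in fm.X.columns:
        cat = cats.get(f)
        if cat in DENSE_CATEGORIES:
            if f in set(univariate.selected) and f in trees:
                final.append(f)
        else:
            if f in set(lasso.selected) and f in trees:
                final.append(f)
    if not final and fallback:
        logger.warning("empty intersection; falling back to demographics")
        final = [f for f in fm.X.columns if cats.get(f) == "demographics"]
    return final


@dataclass
class SelectionBundle:
    final: list[str]
    per_method: dict = field(default_factory=dict)
    intersection_size: int = 0     # before any demographics fallback


def select_features(fm: FeatureMatrix, config: SelectionConfig | None = None,
                    seed: int = 0) -> SelectionBundle:
    """Run all four methods and intersect."""
    config = config or SelectionConfig()
    lasso = adaptive_lasso_select(fm, config, seed=seed)
    uni = univariate_select(fm, config)
    rf, xgb = tree_importance_select(fm, config, seed=seed)
    raw = intersect_features(fm, lasso, uni, rf, xgb, fallback=False)
    final = raw if raw else intersect_features(fm, lasso, uni, rf, xgb)
    return SelectionBundle(final=final, per_method={
        "adaptive_lasso": lasso, "univariate": uni,
        "random_forest": rf, "xgboost": xgb}, intersection_size=len(raw))
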