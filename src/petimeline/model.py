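"""Gradient-boosted timeline models under grouped cross-subject validation.

The modelling objects follow the statsmodels convention: a
:class:`TimepointModel` is built from a feature matrix and fit() returns a
:class:`TimepointResults` carrying the per-fold fitted boosters, held-out
metrics (AUC, sensitivity, specificity, PPV, NPV at a training-set-chosen
threshold), and a ``summary()`` table with the median and interquartile
range across the 10 outer folds.

Fold assignment is cross-subject: every journey of a patient lands in
exactly one fold (StratifiedGroupKFold), with class frequencies
approximately preserved.  Hyperparameters are tuned by seeded random
search over seven families (learning rate, tree count, depth, leaf count,
sample rates, L1/L2 penalties, minimum cases per leaf), scored by mean
inner-fold AUC on a nested grouped split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import ParameterSampler, StratifiedGroupKFold


@dataclass
class FoldPlan:
    """Outer folds of journey positions; all journeys of a patient share a
    fold and class frequencies are approximately preserved."""

    folds: list  # list of (train_idx, test_idx) ndarrays
    seed: int

    def __len__(self) -> int:
        return len(self.folds)

    def class_frequencies(self, y) -> pd.DataFrame:
        y = np.asarray(y, int)
        rows = [{"fold": i, "n": len(te), "pe_fraction": float(y[te].mean())}
                for i, (_, te) in enumerate(self.folds)]
        return pd.DataFrame(rows)


def split_cross_subject(patient_ids, y, k: int = 10, seed: int = 0) -> FoldPlan:
    """Grouped stratified partition of journeys into ``k`` folds."""
    patient_ids = np.asarray(patient_ids)
    y = np.asarray(y, int)
    if len(np.unique(patient_ids)) < k:
        raise ValueError(f"need at least {k} patients for {k} folds")
    sgk = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in sgk.split(np.zeros(len(y)), y, groups=patient_ids)]
    return FoldPlan(folds=folds, seed=seed)


# ------------------------------------------------------------------ metrics

def youden_threshold(y_true, scores) -> float:
    """Operating threshold maximizing Youden's J = SEN + SPE - 1."""
    fpr, tpr, thr = roc_curve(np.asarray(y_true, int), np.asarray(scores, float))
    j = tpr - fpr
    best = int(np.argmax(j))
    t = float(thr[best])
    return min(t, 1.0) if np.isfinite(t) else 0.5


def fixed_specificity_threshold(y_true, scores, specificity: float = 0.90) -> float:
    y_true = np.asarray(y_true, int)
    neg = np.sort(np.asarray(scores, float)[y_true == 0])
    if neg.size == 0:
        return 0.5
    k = int(np.ceil(specificity * neg.size)) - 1
    return float(neg[np.clip(k, 0, neg.size - 1)]) + 1e-12


def evaluate_metrics(y_true, scores, threshold: float) -> dict:
    """Rank AUC plus confusion metrics at the given operating threshold."""
    y = np.asarray(y_true, int)
    s = np.asarray(scores, float)
    single_class = len(np.unique(y)) < 2
    auc = float("nan") if single_class else float(roc_auc_score(y, s))
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return {"auc": auc, "sen": sen, "spe": spe, "ppv": ppv, "npv": npv,
            "prevalence": float(y.mean()), "threshold": float(threshold),
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "auc_undefined": single_class}


def summarize_folds(fold_metrics: pd.DataFrame,
                    metrics: tuple = ("auc", "sen", "spe", "ppv", "npv")) -> pd.DataFrame:
    """Median and first/third quartile of each metric across folds."""
    if len(fold_metrics) < 2:
        raise ValueError("need at least 2 folds to summarize")
    rows = []
    for m in metrics:
        v = fold_metrics[m].dropna().to_numpy(float)
        if v.size == 0:
            rows.append({"metric": m, "median": float("nan"),
                         "q1": float("nan"), "q3": float("nan")})
            continue
        rows.append({"metric": m, "median": float(np.median(v)),
                     "q1": float(np.percentile(v, 25)),
                     "q3": float(np.percentile(v, 75))})
    return pd.DataFrame(rows).set_index("metric")


# ----------------------------------------------------------- hyperparameters

DEFAULT_HYPERPARAMS: dict = {
    "learning_rate": 0.05,
    "n_estimators": 200,
    "max_depth": 6,
    "num_leaves": 31,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "reg_alpha": 0.0,
    "reg_lambda": 0.1,
    "min_child_samples": 20,
}

SEARCH_SPACE: dict = {
    "learning_rate": loguniform(0.005, 0.3),
    "n_estimators": randint(50, 500),
    "max_depth": randint(2, 13),
    "num_leaves": randint(8, 257),
    "subsample": uniform(0.5, 0.5),
    "colsample_bytree": uniform(0.5, 0.5),
    "reg_alpha": loguniform(1e-8, 10.0),
    "reg_lambda": loguniform(1e-8, 10.0),
    "min_child_samples": randint(5, 101),
}


def _make_booster(params: dict, seed: int) -> lgb.LGBMClassifier:
    return lgb.LGBMClassifier(
        **params, random_state=seed, n_jobs=1, verbose=-1,
        deterministic=True, force_row_wise=True)


def tune_hyperparameters(X, y, groups, n_evals: int = 100, k_inner: int = 10,
                         seed: int = 0, search_space: dict | None = None) -> dict:
    """Random search over the seven hyperparameter families; returns the
    configuration with the best mean inner-fold AUC."""
    if n_evals < 1:
        raise ValueError("n_evals must be >= 1")
    space = search_space or SEARCH_SPACE
    X = pd.DataFrame(np.asarray(X, float))
    X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, int)
    k_inner = min(k_inner, len(np.unique(np.asarray(groups))))
    plan = split_cross_subject(groups, y, k=k_inner, seed=seed)
    best_auc, best = -np.inf, None
    for i, params in enumerate(ParameterSampler(space, n_iter=n_evals,
                                                random_state=seed)):
        aucs = []
        for tr, te in plan.folds:
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            clf = _make_booster(params, seed=seed + i)
            clf.fit(X.iloc[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.predict_proba(X.iloc[te])[:, 1]))
        mean_auc = float(np.mean(aucs)) if aucs else -np.inf
        if mean_auc > best_auc:
            best_auc, best = mean_auc, dict(params)
    return {**best, "_inner_auc": best_auc}


# ----------------------------------------------------------------- the model

class TimepointModel:
    """Boosted-tree case/control model for one protocol time point.

    Parameters
    ----------
    X : feature matrix (journeys x features, NaN = missing).
    y : boolean case labels.
    patient_ids : per-journey patient identifiers (grouping unit).
    features : feature subset the model consumes (default: all columns).
    force_include : features added regardless of selection.
    """

    def __init__(self, X: pd.DataFrame, y, patient_ids,
                 features: list[str] | None = None,
                 force_include: list[str] | None = None,
                 timepoint=None):
        self.X_full = X
        self.y = pd.Series(np.asarray(y, bool), index=X.index)
        self.patient_ids = pd.Series(np.asarray(patient_ids), index=X.index)
        feats = list(features) if features is not None else list(X.columns)
        for f in force_include or []:
            if f not in feats and f in X.columns:
                feats.append(f)
        missing = [f for f in feats if f not in X.columns]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        self.features = feats
        self.timepoint = timepoint

    @classmethod
    def from_feature_matrix(cls, fm, features=None, force_include=None):
        return cls(fm.X, fm.y, fm.patient_ids, features=features,
                   force_include=force_include, timepoint=fm.timepoint)

    def fit(self, hyperparams: dict | None = None, k: int = 10, seed: int = 0,
            tune_evals: int = 0, threshold_rule: str = "youden",
            threshold_specificity: float = 0.90) -> "TimepointResults":
        """Fit one booster per outer fold and evaluate on its held-out fold.

        ``tune_evals > 0`` runs nested random-search tuning on the training
        side of the first fold and reuses the winning configuration.
        """
        X = self.X_full[self.features]
        y = self.y.to_numpy(int)
        if len(np.unique(y)) < 2:
            raise ValueError("single-class training data")
        plan = split_cross_subject(self.patient_ids, y, k=k, seed=seed)
        Xv = X.astype(float)

        params = dict(hyperparams) if hyperparams else dict(DEFAULT_HYPERPARAMS)
        if tune_evals > 0:
            tr0 = plan.folds[0][0]
            tuned = tune_hyperparameters(
                Xv.iloc[tr0], y[tr0], self.patient_ids.to_numpy()[tr0],
                n_evals=tune_evals, k_inner=min(10, k), seed=seed)
            params = {k_: v for k_, v in tuned.items() if not k_.startswith("_")}

        models, rows = [], []
        oof = pd.Series(np.nan, index=X.index)
        thresholds = []
        for i, (tr, te) in enumerate(plan.folds):
            if len(np.unique(y[tr])) < 2:
                raise ValueError("single-class training fold")
            clf = _make_booster(params, seed=seed + i)
            clf.fit(Xv.iloc[tr], y[tr])
            s_tr = clf.predict_proba(Xv.iloc[tr])[:, 1]
            if threshold_rule == "youden":
                thr = youden_threshold(y[tr], s_tr)
            elif threshold_rule == "specificity":
                thr = fixed_specificity_threshold(y[tr], s_tr, threshold_specificity)
            else:
                raise ValueError(f"unknown threshold rule {threshold_rule!r}")
            s_te = clf.predict_proba(Xv.iloc[te])[:, 1]
            m = evaluate_metrics(y[te], s_te, thr)
            m["fold"] = i
            rows.append(m)
            models.append(clf)
            thresholds.append(thr)
            oof.iloc[te] = s_te
        fold_metrics = pd.DataFrame(rows).set_index("fold")
        return TimepointResults(
            model=self, params=params, fold_plan=plan, models=models,
            fold_metrics=fold_metrics, oof_scores=oof, thresholds=thresholds)


@dataclass
class TimepointResults:
    """Fit results: per-fold boosters, held-out metrics, fold plan."""

    model: TimepointModel
    params: dict
    fold_plan: FoldPlan
    models: list = field(default_factory=list)
    fold_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    oof_scores: pd.Series = field(default_factory=pd.Series)
    thresholds: list = field(default_factory=list)

    @property
    def features(self) -> list[str]:
        return self.model.features

    def summary(self) -> pd.DataFrame:
        """Median [Q1, Q3] of AUC / SEN / SPE / PPV / NPV across folds."""
        return summarize_folds(self.fold_metrics)

    def predict(self, X: pd.DataFrame, fold: int = 0) -> np.ndarray:
        return self.models[fold].predict_proba(X[self.features].astype(float))[:, 1]

    def median(self, metric: str) -> float:
        return float(self.fold_metrics[metric].median())


def train_timeline_model(fm, selected_features, hyperparams=None,
                         force_include=None, k: int = 10, seed: int = 0) -> TimepointResults:
    """Functional wrapper over :class:`TimepointModel` for one time point."""
    model = TimepointModel.from_feature_matrix(
        fm, features=selected_features, force_include=force_include)
    return model.fit(hyperparams=hyperparams, k=k, seed=seed)
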