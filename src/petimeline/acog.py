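"""Guideline criteria-based comparator.

The standard-of-care risk assessment sums binary risk factors: six
high-risk factors (history of preeclampsia, multifetal gestation, chronic
hypertension, type 1/2 diabetes, renal disease, autoimmune disease) and
six moderate-risk factors (nulliparity, obesity BMI > 30, family history
of preeclampsia, sociodemographic characteristics, age >= 35, personal
history factors).  Composite factors (sociodemographic, personal history)
count once if any member is present.  The raw score is used directly as a
classifier statistic; its AUC is summarized over bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .config import ACOG_HIGH_FACTORS, ACOG_MODERATE_FACTORS, CodeSets


@dataclass
class AcogScores:
    """Per-journey factor flags and risk scores."""

    factors: pd.DataFrame   # binary flags, one column per factor
    high: pd.Series
    moderate: pd.Series
    total: pd.Series


def acog_risk_score(factors: pd.DataFrame) -> AcogScores:
    """Sum binary high- and moderate-risk factor flags.

    Missing factor columns count as absent; extra columns are ignored.
    """
    f = pd.DataFrame(index=factors.index)
    for c in ACOG_HIGH_FACTORS + ACOG_MODERATE_FACTORS:
        f[c] = factors[c].fillna(0).astype(int) if c in factors.columns else 0
    high = f[list(ACOG_HIGH_FACTORS)].sum(axis=1)
    moderate = f[list(ACOG_MODERATE_FACTORS)].sum(axis=1)
    return AcogScores(factors=f, high=high, moderate=moderate, total=high + moderate)


def acog_factors_from_cohort(ehr, journeys: pd.DataFrame,
                             code_sets: CodeSets | None = None) -> pd.DataFrame:
    """Derive the guideline factor flags from baseline/antepartum records.

    Diagnosis-code factors use any code in the journey window up to
    admission; obesity uses the earliest weight and height in the window.
    """
    code_sets = code_sets or CodeSets()
    jn = journeys.set_index("journey_id")
    pat = ehr.patients.set_index("patient_id").loc[jn["patient_id"]]
    pat.index = jn.index

    out = pd.DataFrame(index=jn.index)
    out["history_of_preeclampsia"] = pat["prior_pe"].to_numpy(int)
    out["nulliparity"] = (pat["parity"].to_numpy(int) == 0).astype(int)
    out["family_history_preeclampsia"] = pat["family_history_pe"].to_numpy(int)
    out["personal_history_factors"] = pat["personal_history_factors"].to_numpy(int)
    age = ((jn["pregnancy_start"].to_numpy() - pat["birth_date"].to_numpy())
           / np.timedelta64(1, "D") / 365.25)
    out["age_35_or_older"] = (age >= 35).astype(int)
    black = pat["race"].astype(str).str.contains("African American")
    out["sociodemographic"] = (black | (pat["medicaid"] == 1)).astype(int).to_numpy()

    dx_factor_codes = {
        "chronic_hypertension": {"DX_CHTN"},
        "diabetes": {"DX_DM"},
        "renal_disease": {"DX_RENAL"},
        "autoimmune_disease": {"DX_AUTOIMM"},
        "multifetal_gestation": {"DX_MULTIFETAL"},
    }
    dx = ehr.diagnoses.merge(
        jn.reset_index()[["journey_id", "patient_id", "window_start", "admission"]],
        on="patient_id")
    dx = dx[(dx["date"] >= dx["window_start"]) & (dx["date"] < dx["admission"])]
    for factor, codes in dx_factor_codes.items():
        hits = dx.loc[dx["code"].isin(codes), "journey_id"].unique()
        out[factor] = out.index.isin(hits).astype(int)

    vit = ehr.vitals.merge(
        jn.reset_index()[["journey_id", "patient_id", "window_start", "admission"]],
        on="patient_id")
    vit = vit[(vit["datetime"] >= vit["window_start"]) &
              (vit["datetime"] < vit["admission"])]
    vit = vit.sort_values("datetime", kind="mergesort")
    first = vit.groupby(["journey_id", "type"])["value"].first().unstack("type")
    bmi = pd.Series(np.nan, index=out.index)
    if "weight" in first.columns and "height" in first.columns:
        f = first.reindex(out.index)
        bmi = f["weight"] / (f["height"] / 100.0) ** 2
    out["obesity"] = (bmi > 30).fillna(False).astype(int)
    return out


def acog_auc_bootstrap(scores, labels, frac: float = 0.90, reps: int = 1000,
                       seed: int = 0) -> dict:
    """AUC of the raw risk score over bootstrap replicates.

    Each replicate samples ``frac`` of the data with replacement; reports
    median, first/third quartile (and mean) of the replicate AUCs.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    rng = np.random.default_rng(seed)
    m = int(round(frac * len(y)))
    aucs = []
    for _ in range(reps):
        idx = rng.integers(0, len(y), size=m)
        if len(np.unique(y[idx])) < 2:
            continue
        if np.all(s[idx] == s[idx][0]):
            aucs.append(0.5)  # constant score carries no ranking information
            continue
        aucs.append(float(roc_auc_score(y[idx], s[idx])))
    aucs = np.asarray(aucs)
    return {"median": float(np.median(aucs)), "q1": float(np.percentile(aucs, 25)),
            "q3": float(np.percentile(aucs, 75)), "mean": float(np.mean(aucs)),
            "n_replicates": int(aucs.size), "aucs": aucs}
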