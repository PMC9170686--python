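"""Pregnancy-journey reconstruction.

Delivery events are identified from three evidence paths — delivery
diagnosis codes, delivery procedure codes (vaginal/cesarean) and
labor-and-delivery admissions — restricted to biologically female patients
aged 12-50 at the event, with nearby evidence merged into a single event.
Pregnancy start is dated from gestational-week reports
(``report_date - 7 * gestational_week``), and each journey carries a data
window from 240 days (8 months) before pregnancy start to 70 days (10
weeks) after delivery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CodeSets, ConfigurationError

PREPREGNANCY_DAYS = 240
POSTPARTUM_DAYS = 70
DEDUP_WINDOW_DAYS = 180
MIN_AGE, MAX_AGE = 12, 50


@dataclass
class JourneyConfig:
    prepregnancy_days: int = PREPREGNANCY_DAYS
    postpartum_days: int = POSTPARTUM_DAYS
    dedup_window_days: int = DEDUP_WINDOW_DAYS
    min_gestational_week: int = 1
    max_gestational_week: int = 45
    gw_conflict_rule: str = "latest"   # or "median"
    sparsity_min_events: int = 1       # non-demographic events required in window


def compute_pregnancy_start(report_date: pd.Timestamp, gestational_week: int) -> pd.Timestamp:
    """Pregnancy start = report date minus 7 x gestational week days."""
    if gestational_week <= 0:
        raise ValueError(f"gestational_week must be positive, got {gestational_week}")
    return pd.Timestamp(report_date) - pd.Timedelta(days=7 * int(gestational_week))


def identify_deliveries(ehr, code_sets: CodeSets | None = None,
                        config: JourneyConfig | None = None) -> pd.DataFrame:
    """Find standalone delivery events.

    Returns one row per event: patient_id, admission, delivery, mode and the
    evidence flags.  Candidate evidence closer together than the dedup
    window is merged into one event (two true deliveries cannot be that
    close).
    """
    if code_sets is None:
        raise ConfigurationError("code_sets are required to identify deliveries")
    config = config or JourneyConfig()

    cands = []
    dx = ehr.diagnoses
    m = dx["code"].isin(code_sets.delivery_diagnosis)
    cands.append(pd.DataFrame({
        "patient_id": dx.loc[m, "patient_id"], "when": dx.loc[m, "date"],
        "kind": "dx", "mode": "unknown"}))
    pr = ehr.procedures
    for codes, mode in ((code_sets.cesarean_procedures, "cesarean"),
                        (code_sets.vaginal_procedures, "vaginal")):
        m = pr["code"].isin(codes)
        cands.append(pd.DataFrame({
            "patient_id": pr.loc[m, "patient_id"], "when": pr.loc[m, "date"],
            "kind": "procedure", "mode": mode}))
    adm = ehr.admissions
    m = adm["labor_and_delivery"] == 1
    cands.append(pd.DataFrame({
        "patient_id": adm.loc[m, "patient_id"], "when": adm.loc[m, "admit_datetime"],
        "kind": "admission", "mode": "unknown"}))
    cands = [c for c in cands if len(c)]
    cand = pd.concat(cands, ignore_index=True) if cands else pd.DataFrame(
        columns=["patient_id", "when", "kind", "mode"])
    if cand.empty:
        return pd.DataFrame(columns=["patient_id", "admission", "delivery", "mode",
                                     "ev_diagnosis", "ev_procedure", "ev_admission"])

    cand["when"] = pd.to_datetime(cand["when"])
    cand = cand.sort_values(["patient_id", "when"], kind="mergesort")
    # merge evidence within the dedup window into one event per cluster
    same = cand["patient_id"].eq(cand["patient_id"].shift())
    gap = cand["when"].diff().dt.total_seconds() / 86400.0
    cand["cluster"] = (~(same & (gap < config.dedup_window_days))).cumsum()

    def _collapse(g: pd.DataFrame) -> pd.Series:
        proc = g[g["kind"] == "procedure"]
        dxg = g[g["kind"] == "dx"]
        admg = g[g["kind"] == "admission"]
        if len(proc):
            delivery = proc["when"].iloc[0]
        elif len(dxg):
            delivery = dxg["when"].iloc[0]
        else:
            delivery = g["when"].max()
        admission = admg["when"].min() if len(admg) else delivery
        mode = proc["mode"].iloc[0] if len(proc) else "unknown"
        return pd.Series({
            "patient_id": g["patient_id"].iloc[0],
            "admission": min(admission, delivery), "delivery": delivery, "mode": mode,
            "ev_diagnosis": bool(len(dxg)), "ev_procedure": bool(len(proc)),
            "ev_admission": bool(len(admg))})

    events = cand.groupby("cluster", sort=True).apply(_collapse, include_groups=False)
    events = events.reset_index(drop=True)

    pat = ehr.patients.set_index("patient_id")
    events = events[events["patient_id"].isin(pat.index)]
    sex = pat.loc[events["patient_id"], "sex"].to_numpy()
    birth = pd.DatetimeIndex(pat.loc[events["patient_id"], "birth_date"])
    age = (events["delivery"].to_numpy() - birth.to_numpy()) / np.timedelta64(1, "D") / 365.25
    keep = (sex == "F") & (age >= MIN_AGE) & (age <= MAX_AGE)
    return events[keep].reset_index(drop=True)


def assemble_journeys(ehr, deliveries: pd.DataFrame,
                      config: JourneyConfig | None = None,
                      return_rejections: bool = False):
    """Attach pregnancy start dates and data windows to delivery events.

    Start comes from the gestational-week report implying the latest start
    under the configured conflict rule; deliveries with no usable report,
    and journeys whose window holds no non-demographic data beyond the
    delivery evidence itself, are rejected (logged, not fatal).
    """
    config = config or JourneyConfig()
    gw = ehr.gw_reports
    ok_week = (gw["gestational_week"] >= config.min_gestational_week) & \
              (gw["gestational_week"] <= config.max_gestational_week)
    gw = gw[ok_week].copy()
    gw["implied_start"] = gw["report_date"] - pd.to_timedelta(
        7 * gw["gestational_week"], unit="D")

    rows, rejects = [], []
    gw_by_pat = dict(tuple(gw.groupby("patient_id", sort=False)))
    for i, ev in deliveries.iterrows():
        reports = gw_by_pat.get(ev["patient_id"])
        if reports is not None:
            lookback = ev["delivery"] - pd.Timedelta(days=310)
            reports = reports[(reports["report_date"] <= ev["delivery"]) &
                              (reports["report_date"] > lookback)]
        if reports is None or len(reports) == 0:
            rejects.append({"patient_id": ev["patient_id"], "delivery": ev["delivery"],
                            "reason": "no_gestational_week_report"})
            continue
        if config.gw_conflict_rule == "median":
            start = reports["implied_start"].median().floor("D")
        else:  # latest report is closest to delivery and least extrapolated
            start = reports.loc[reports["report_date"].idxmax(), "implied_start"]
        start = pd.Timestamp(start).floor("D")
        if start >= ev["admission"]:
            rejects.append({"patient_id": ev["patient_id"], "delivery": ev["delivery"],
                            "reason": "implausible_start"})
            continue
        rows.append({
            "patient_id": ev["patient_id"], "pregnancy_start": start,
            "admission": ev["admission"], "delivery": ev["delivery"], "mode": ev["mode"],
            "window_start": start - pd.Timedelta(days=config.prepregnancy_days),
            "window_end": ev["delivery"] + pd.Timedelta(days=config.postpartum_days),
        })

    journeys = pd.DataFrame(rows, columns=["patient_id", "pregnancy_start", "admission",
                                           "delivery", "mode", "window_start", "window_end"])
    if len(journeys):
        counts = _window_event_counts(ehr, journeys, config)
        sparse = counts < config.sparsity_min_events
        for _, r in journeys[sparse].iterrows():
            rejects.append({"patient_id": r["patient_id"], "delivery": r["delivery"],
                            "reason": "sparse_journey"})
        journeys = journeys[~sparse].reset_index(drop=True)
    if len(journeys):
        journeys["gestational_length_days"] = (
            (journeys["delivery"].dt.normalize() - journeys["pregnancy_start"])
            .dt.days.astype(int))
        journeys.insert(0, "journey_id", [
            f"{p}-J{k}" for p, k in zip(
                journeys["patient_id"],
                journeys.groupby("patient_id", sort=False).cumcount())])
    else:
        journeys["gestational_length_days"] = pd.Series(dtype=int)
        journeys.insert(0, "journey_id", pd.Series(dtype=object))
    rejections = pd.DataFrame(rejects, columns=["patient_id", "delivery", "reason"])
    if return_rejections:
        return journeys, rejections
    return journeys


def _window_event_counts(ehr, journeys: pd.DataFrame, config: JourneyConfig) -> np.ndarray:
    """Sparsity-filter support: count non-demographic events inside each
    journey window, excluding delivery evidence within 1 day of delivery."""
    counts = np.zeros(len(journeys), dtype=int)
    if not len(journeys):
        return counts
    idx = journeys.reset_index(drop=True)
    for table, col, excl in (("diagnoses", "date", True), ("medications", "date", False),
                             ("procedures", "date", True), ("vitals", "datetime", False),
                             ("labs", "datetime", False)):
        df = getattr(ehr, table)[["patient_id"]].assign(
            t=pd.to_datetime(getattr(ehr, table)[col]))
        merged = df.merge(
            idx[["patient_id", "window_start", "window_end", "delivery"]]
            .reset_index(names="ev_i"), on="patient_id", how="inner")
        m = (merged["t"] >= merged["window_start"]) & (merged["t"] <= merged["window_end"])
        if excl:
            m &= (merged["t"] - merged["delivery"]).abs() > pd.Timedelta(days=1)
        np.add.at(counts, merged.loc[m, "ev_i"].to_numpy(), 1)
    return counts


def build_journeys(ehr, code_sets: CodeSets | None = None,
                   config: JourneyConfig | None = None,
                   return_rejections: bool = False):
    """Convenience wrapper: identify deliveries then assemble journeys."""
    code_sets = code_sets or CodeSets()
    deliveries = identify_deliveries(ehr, code_sets, config)
    return assemble_journeys(ehr, deliveries, config, return_rejections=return_rejections)
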