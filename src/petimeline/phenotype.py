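"""Rule-based digital phenotyping of preeclampsia.

Two paths assign case status within the at-risk window
[gestational week 20, delivery + 70 days]:

* **Code path** — a preeclampsia diagnosis code inside the window; onset is
  the first such code date.
* **Rule path** — a hypertension episode (two distinct readings with
  SBP >= 140 or DBP >= 90 no more than 3 days apart) whose first reading is
  followed, within 3 days either side, by proteinuria evidence (a
  proteinuria diagnosis code, a dipstick urine-protein reading of "small"
  or worse, or a quantitative urine protein above threshold); onset is the
  first high-blood-pressure day.

When both paths fire, the code path dates the onset (the rule path exists
to capture undiagnosed cases).  Subtype follows onset relative to the
labor-and-delivery admission and the delivery: antepartum before admission,
intrapartum between admission and delivery, postpartum after delivery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CodeSets, PhenotypeConfig
from .features import clean_vitals, encode_lab_ordinal_series

logger = logging.getLogger(__name__)


@dataclass
class HypertensionEpisode:
    """A qualifying repeated-high-blood-pressure episode."""

    first_high_bp: pd.Timestamp
    second_high_bp: pd.Timestamp
    readings: list = field(default_factory=list)


def _qualifying_bp_times(bp: pd.DataFrame, config: PhenotypeConfig) -> pd.Series:
    """Distinct timestamps of readings with SBP or DBP at/above threshold."""
    high = pd.Series(False, index=bp.index)
    if "sbp" in bp.columns:
        high |= bp["sbp"] >= config.sbp_threshold
    if "dbp" in bp.columns:
        high |= bp["dbp"] >= config.dbp_threshold
    times = bp.loc[high.fillna(False), "datetime"]
    return times.drop_duplicates().sort_values()


def detect_hypertension_episode(bp_series: pd.DataFrame,
                                search_window: tuple | None = None,
                                config: PhenotypeConfig | None = None):
    """Earliest episode of two qualifying readings within the pair window.

    ``bp_series`` is a frame with columns ``datetime`` and ``sbp`` and/or
    ``dbp``; readings are assumed plausibility-filtered.  Returns a
    :class:`HypertensionEpisode` or ``None``.  Distinct timestamps count as
    distinct readings ("at least twice"), so a single visit recording both
    a high SBP and a high DBP is one reading, not two.
    """
    config = config or PhenotypeConfig()
    if bp_series is None or len(bp_series) == 0:
        return None
    bp = bp_series
    if search_window is not None:
        t0, t1 = search_window
        bp = bp[(bp["datetime"] >= t0) & (bp["datetime"] <= t1)]
    times = _qualifying_bp_times(bp, config).to_numpy()
    if times.size < 2:
        return None
    window = np.timedelta64(int(config.pair_window_days * 86400), "s")
    gaps = np.diff(times)
    hits = np.flatnonzero(gaps <= window)
    if hits.size == 0:
        return None
    first = times[hits[0]]
    second = times[hits[0] + 1]
    in_episode = (times >= first) & (times <= first + window)
    return HypertensionEpisode(first_high_bp=pd.Timestamp(first),
                               second_high_bp=pd.Timestamp(second),
                               readings=[pd.Timestamp(t) for t in times[in_episode]])


def detect_proteinuria(diagnoses: pd.DataFrame, labs: pd.DataFrame,
                       anchor: pd.Timestamp,
                       code_sets: CodeSets | None = None,
                       config: PhenotypeConfig | None = None):
    """Earliest proteinuria evidence within the evidence window of ``anchor``.

    Evidence sources: a proteinuria diagnosis code, a descriptive
    urine-protein result at or above the ordinal threshold, or a
    quantitative urine protein at/above the configured threshold.  Returns
    ``{"kind", "datetime"}`` or ``None``.
    """
    code_sets = code_sets or CodeSets()
    config = config or PhenotypeConfig()
    window = pd.Timedelta(days=config.evidence_window_days)
    events = []
    if diagnoses is not None and len(diagnoses):
        m = diagnoses["code"].isin(code_sets.proteinuria_diagnosis)
        for t in diagnoses.loc[m, "date"]:
            events.append(("diagnosis", t))
    if labs is not None and len(labs):
        urine = labs[labs["analyte"].isin(code_sets.urine_protein_analytes)]
        if len(urine):
            ordv = encode_lab_ordinal_series(urine.get("value_text"))
            numv = pd.to_numeric(urine.get("value_numeric"), errors="coerce")
            hit = (ordv >= config.ordinal_threshold) | \
                  (numv >= config.quantitative_threshold)
            for t in urine.loc[hit.fillna(False).to_numpy(), "datetime"]:
                events.append(("lab", t))
    events = [(k, t) for k, t in events if abs(t - anchor) <= window]
    if not events:
        return None
    kind, t = min(events, key=lambda kt: kt[1])
    return {"kind": kind, "datetime": pd.Timestamp(t)}


def _merge_window(df: pd.DataFrame, journeys: pd.DataFrame, timecol: str) -> pd.DataFrame:
    """Attach journey ids to events falling inside each journey window."""
    j = journeys[["journey_id", "patient_id", "window_start", "window_end"]]
    merged = df.merge(j, on="patient_id", how="inner")
    inside = (merged[timecol] >= merged["window_start"]) & \
             (merged[timecol] <= merged["window_end"])
    n_out = int((~inside).sum())
    if n_out:
        logger.info("ignoring %d events outside journey windows", n_out)
    return merged[inside].drop(columns=["window_start", "window_end"])


def phenotype_journeys(ehr, journeys: pd.DataFrame,
                       code_sets: CodeSets | None = None,
                       config: PhenotypeConfig | None = None) -> pd.DataFrame:
    """Label every journey (vectorized across the cohort).

    Returns one row per journey: ``journey_id, is_pe, onset, subtype,
    source, has_htn_episode`` with source in {icd, rule, both, none}.
    """
    code_sets = code_sets or CodeSets()
    config = config or PhenotypeConfig()
    jn = journeys.reset_index(drop=True)
    n = len(jn)
    gw20 = jn["pregnancy_start"] + pd.Timedelta(days=7 * config.onset_min_gestational_week)
    jid = jn["journey_id"]
    lookup = pd.Series(np.arange(n), index=jid)

    # --- code path ---------------------------------------------------------
    icd_onset = pd.Series(pd.NaT, index=np.arange(n))
    dx = ehr.diagnoses
    pe_dx = dx[dx["code"].isin(code_sets.pe_diagnosis)]
    if len(pe_dx):
        m = _merge_window(pe_dx, jn, "date")
        m = m[(m["date"] >= gw20.iloc[lookup[m["journey_id"]].to_numpy()].to_numpy())]
        first = m.groupby("journey_id")["date"].min()
        icd_onset.loc[lookup[first.index].to_numpy()] = first.to_numpy()

    # --- rule path: hypertension episodes ----------------------------------
    vit = clean_vitals(ehr.vitals)
    bp = vit[vit["type"].isin(("sbp", "dbp"))]
    high = ((bp["type"] == "sbp") & (bp["value"] >= config.sbp_threshold)) | \
           ((bp["type"] == "dbp") & (bp["value"] >= config.dbp_threshold))
    bp = bp[high]
    anchor = pd.Series(pd.NaT, index=np.arange(n))
    if len(bp):
        m = _merge_window(bp[["patient_id", "datetime"]], jn, "datetime")
        m = m[m["datetime"] >= gw20.iloc[lookup[m["journey_id"]].to_numpy()].to_numpy()]
        m = m.drop_duplicates(["journey_id", "datetime"])
        m = m.sort_values(["journey_id", "datetime"], kind="mergesort")
        same = m["journey_id"].eq(m["journey_id"].shift(-1))
        gap = m["datetime"].shift(-1) - m["datetime"]
        pair_ok = same & (gap <= pd.Timedelta(days=config.pair_window_days))
        firsts = m[pair_ok].groupby("journey_id")["datetime"].min()
        anchor.loc[lookup[firsts.index].to_numpy()] = firsts.to_numpy()

    # --- rule path: proteinuria evidence near the anchor --------------------
    ev_frames = []
    protu_dx = dx[dx["code"].isin(code_sets.proteinuria_diagnosis)]
    if len(protu_dx):
        ev_frames.append(protu_dx[["patient_id", "date"]].rename(columns={"date": "t"}))
    labs = ehr.labs
    urine = labs[labs["analyte"].isin(code_sets.urine_protein_analytes)]
    if len(urine):
        ordv = encode_lab_ordinal_series(urine["value_text"])
        numv = pd.to_numeric(urine["value_numeric"], errors="coerce")
        hit = ((ordv >= config.ordinal_threshold) |
               (numv >= config.quantitative_threshold)).fillna(False).to_numpy()
        ev_frames.append(urine.loc[hit, ["patient_id", "datetime"]]
                         .rename(columns={"datetime": "t"}))
    rule_fire = np.zeros(n, dtype=bool)
    if ev_frames:
        ev = pd.concat(ev_frames, ignore_index=True)
        m = _merge_window(ev, jn, "t")
        ji = lookup[m["journey_id"]].to_numpy()
        anc = anchor.iloc[ji].to_numpy()
        near = np.abs(m["t"].to_numpy() - anc) <= np.timedelta64(
            int(config.evidence_window_days * 86400), "s")
        np.logical_or.at(rule_fire, ji[near & ~pd.isna(anc)], True)

    # --- combine ------------------------------------------------------------
    has_icd = icd_onset.notna().to_numpy()
    has_episode = anchor.notna().to_numpy()
    rule_fire &= has_episode
    is_pe = has_icd | rule_fire
    onset = np.where(has_icd, icd_onset.to_numpy(), anchor.to_numpy())
    onset = pd.Series(onset).where(is_pe, pd.NaT)
    source = np.select(
        [has_icd & rule_fire, has_icd, rule_fire],
        ["both", "icd", "rule"], default="none")

    adm = jn["admission"].to_numpy()
    dlv = jn["delivery"].to_numpy()
    ons = onset.to_numpy()
    subtype = np.select(
        [is_pe & (ons < adm), is_pe & (ons <= dlv), is_pe & (ons > dlv)],
        ["antepartum", "intrapartum", "postpartum"], default="none")

    return pd.DataFrame({
        "journey_id": jid.to_numpy(), "is_pe": is_pe, "onset": onset.to_numpy(),
        "subtype": subtype, "source": source, "has_htn_episode": has_episode,
    })


def phenotype_journey(journey: pd.Series, ehr,
                      code_sets: CodeSets | None = None,
                      config: PhenotypeConfig | None = None) -> pd.Series:
    """Label a single journey; see :func:`phenotype_journeys`."""
    one = journey.to_frame().T
    one = one.infer_objects()
    return phenotype_journeys(ehr, one, code_sets, config).iloc[0]


def validate_against_icd(labels: pd.DataFrame) -> dict:
    """Concordance of the code path with rule evidence.

    Among code-identified cases, reports the fraction carrying rule
    evidence (a qualifying hypertension episode, with or without anchored
    proteinuria).  With zero code-identified cases the fraction is
    undefined and flagged.
    """
    icd_cases = labels[labels["source"].isin(("icd", "both"))]
    n_icd = len(icd_cases)
    if n_icd == 0:
        return {"n_icd": 0, "n_with_rule_evidence": 0, "fraction": float("nan"),
                "undefined": True}
    with_rule = int((icd_cases["has_htn_episode"] |
                     (icd_cases["source"] == "both")).sum())
    return {"n_icd": n_icd, "n_with_rule_evidence": with_rule,
            "fraction": with_rule / n_icd, "undefined": False}
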