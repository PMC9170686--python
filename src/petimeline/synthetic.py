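"""Seeded synthetic EMR generator.

Emits relational event tables (patients, admissions, diagnoses, medications,
procedures, vitals, labs, gestational-week reports) with the statistical
structure the downstream analysis assumes:

* ~9.3% of pregnancy journeys develop preeclampsia, split into antepartum /
  intrapartum / postpartum subtypes;
* cases carry systolic blood pressure ~10 mmHg above controls, ramping in
  over the six weeks before clinical onset but usually staying in the
  normal range;
* cases show a shifted dipstick urine-protein distribution (more trace and
  low-grade positives), fibrinogen rising from gestational week 16, and
  slightly lower mean corpuscular hemoglobin;
* only a configurable minority of cases receive an explicit diagnosis code,
  and a configurable fraction of those also carry rule evidence (a repeated
  >=140/90 blood-pressure episode plus proteinuria within three days);
* visits follow the prenatal protocol schedule with Gaussian jitter and
  Bernoulli missingness.

Everything is driven by one ``numpy`` Generator, so a seed fully determines
the output.  The planted ground truth is attached as ``RawEHR.truth`` for
validation; it is not part of the EMR tables themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError, GeneratorConfig

EPOCH = pd.Timestamp("2000-01-01")

PROTOCOL_WEEKS = (4, 8, 12, 16, 20, 22, 24, 26, 28, 30, 32, 34, 35, 36, 37, 38, 39)

_RACES = ("African American", "Asian", "Caucasian", "Hispanic", "Native American", "Other")
_RACE_P = (0.14, 0.08, 0.53, 0.16, 0.01, 0.08)

_ORDINAL_TEXT = ("negative", "trace", "small", "moderate", "large")
_URINE_P_CONTROL = (0.850, 0.120, 0.020, 0.007, 0.003)
_URINE_P_PE = (0.650, 0.220, 0.080, 0.040, 0.010)

_IMPLAUSIBLE = {
    "sbp": 400.0, "dbp": 395.0, "pulse": 350.0, "temperature": 50.0,
    "weight": 1000.0, "height": 300.0, "o2_saturation": 120.0, "respirations": 200.0,
}
_VITAL_UNITS = {
    "sbp": "mmHg", "dbp": "mmHg", "pulse": "Beats/Min", "temperature": "DegF",
    "weight": "kg", "height": "cm", "o2_saturation": "%", "respirations": "/min",
    "pain": "0-10",
}

TABLE_NAMES = ("patients", "admissions", "diagnoses", "medications", "procedures",
               "vitals", "labs", "gw_reports", "truth")


@dataclass
class RawEHR:
    """Bundle of relational EMR tables; ``truth`` holds the planted journey
    ground truth (synthetic only, never consumed by the pipeline)."""

    patients: pd.DataFrame
    admissions: pd.DataFrame
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    procedures: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    gw_reports: pd.DataFrame
    truth: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}


def _days_to_dt(days: np.ndarray) -> pd.Series:
    """Float day offsets from EPOCH -> second-resolution timestamps."""
    return (EPOCH + pd.to_timedelta(np.round(np.asarray(days, float) * 86400.0), unit="s"))


def _journey_skeletons(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_total = config.n_patients
    n_male = int(round(n_total * config.male_fraction))
    n_female = n_total - n_male
    n_j = 1 + rng.poisson(config.journeys_per_patient_mean - 1.0, size=n_female)

    pid_idx = np.repeat(np.arange(n_female), n_j)
    order = np.concatenate([np.arange(k) for k in n_j])

    gest = np.clip(rng.normal(config.journey_length_mean, config.journey_length_sd,
                              size=pid_idx.size), 245, 295)
    first_start = rng.uniform(2920.0, 6570.0, size=n_female)  # 2008..2017
    gaps = rng.uniform(250.0, 700.0, size=pid_idx.size)
    start = np.empty(pid_idx.size)
    pos = 0
    for i, k in enumerate(n_j):
        s = first_start[i]
        for j in range(k):
            start[pos] = s
            s += gest[pos] + gaps[pos]
            pos += 1
    delivery = start + gest + rng.uniform(0.3, 0.9, size=start.size)
    admission = delivery - rng.uniform(4.0, 30.0, size=start.size) / 24.0

    return pd.DataFrame({
        "patient_idx": pid_idx, "journey_order": order,
        "start": start, "admission": admission, "delivery": delivery,
        "gest_days": delivery - start,
    })


def assign_pe_scenarios(skeletons: pd.DataFrame, config: GeneratorConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plant case status, subtype, onset time and coding flags per journey.

    Antepartum onsets fall in [gestational week 20, admission); intrapartum
    in [admission, delivery]; postpartum in (delivery, delivery + 70d].
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    sk = skeletons.copy()
    n = len(sk)
    is_pe = rng.random(n) < config.pe_prevalence
    w = config.normalized_subtype_weights()
    subtype_idx = rng.choice(3, size=n, p=w if sum(w) > 0 else None)
    subtype = np.where(is_pe, subtype_idx, -1)

    start = sk["start"].to_numpy()
    adm = sk["admission"].to_numpy()
    dlv = sk["delivery"].to_numpy()
    u = rng.random(n)
    onset = np.full(n, np.nan)
    ante = is_pe & (subtype == 0)
    intra = is_pe & (subtype == 1)
    post = is_pe & (subtype == 2)
    lo = start + 141.0
    hi = np.maximum(adm - 2.0, lo + 1.0)
    onset[ante] = (lo + u * (hi - lo))[ante]
    onset[intra] = (adm + u * (dlv - adm))[intra]
    onset[post] = (dlv + 1.0 + u * 69.0)[post]

    icd = is_pe & (rng.random(n) < config.icd_coding_rate)
    rule = is_pe & np.where(icd, rng.random(n) < config.rule_evidence_rate_given_icd, True)

    sk["is_pe"] = is_pe
    sk["subtype"] = np.select([ante, intra, post], ["antepartum", "intrapartum", "postpartum"],
                              default="none")
    sk["onset"] = onset
    sk["icd_coded"] = icd
    sk["rule_evidence"] = rule
    return sk


def _make_patients(sk: pd.DataFrame, n_female: int, n_male: int, config: GeneratorConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    any_pe = np.zeros(n_female, bool)
    np.logical_or.at(any_pe, sk["patient_idx"].to_numpy(), sk["is_pe"].to_numpy())
    first_start = np.full(n_female, np.inf)
    np.minimum.at(first_start, sk["patient_idx"].to_numpy(), sk["start"].to_numpy())

    age = np.clip(rng.normal(31.0 + 1.5 * any_pe, 6.0), 16.0, 48.0)
    birth = first_start - age * 365.25

    race_idx = rng.choice(len(_RACES), size=n_female, p=_RACE_P)
    race = np.array(_RACES, dtype=object)[race_idx]
    multi = rng.random(n_female) < 0.01
    second = np.array(_RACES, dtype=object)[rng.choice(len(_RACES), size=n_female)]
    race = np.where(multi & (second != race), race + ";" + second, race)

    def bern(p_ctl, p_pe):
        return (rng.random(n_female) < np.where(any_pe, p_pe, p_ctl)).astype(int)

    female = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n_female)],
        "birth_date": pd.DatetimeIndex(_days_to_dt(birth)).normalize(),
        "sex": "F",
        "race": race,
        "medicaid": bern(0.35, 0.45),
        "smoking_history": bern(0.09, 0.12),
        "alcohol_history": bern(0.14, 0.14),
        "parity": rng.poisson(0.9, size=n_female),
        "prior_pe": bern(0.004, 0.06),
        "family_history_pe": bern(0.010, 0.030),
        "personal_history_factors": bern(0.02, 0.04),
        "chronic_htn": bern(0.04, 0.15),
        "diabetes": bern(0.03, 0.08),
        "renal_disease": bern(0.005, 0.02),
        "autoimmune_disease": bern(0.005, 0.02),
    })
    male = pd.DataFrame({
        "patient_id": [f"M{i:06d}" for i in range(n_male)],
        "birth_date": pd.DatetimeIndex(_days_to_dt(rng.uniform(-3650, 3650, n_male))).normalize(),
        "sex": "M", "race": rng.choice(_RACES, size=n_male),
        "medicaid": rng.integers(0, 2, n_male), "smoking_history": 0, "alcohol_history": 0,
        "parity": 0, "prior_pe": 0, "family_history_pe": 0, "personal_history_factors": 0,
        "chronic_htn": 0, "diabetes": 0, "renal_disease": 0, "autoimmune_disease": 0,
    })
    return pd.concat([female, male], ignore_index=True)


def _visit_frame(sk: pd.DataFrame, config: GeneratorConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Long table of attended encounters: one row per (journey, visit)."""
    n = len(sk)
    start = sk["start"].to_numpy()
    adm = sk["admission"].to_numpy()
    dlv = sk["delivery"].to_numpy()
    parts = []

    # pre-pregnancy baseline encounter, always attended
    parts.append(pd.DataFrame({
        "j": np.arange(n), "day": start - rng.uniform(10.0, 230.0, n), "kind": "baseline"}))

    for w in PROTOCOL_WEEKS:
        day = start + 7.0 * w + rng.normal(0.0, config.visit_jitter_sd, n)
        keep = (rng.random(n) < config.visit_attendance) & (day < adm - 1.0) & (day > start)
        parts.append(pd.DataFrame({"j": np.flatnonzero(keep), "day": day[keep],
                                   "kind": "antepartum"}))

    for k in range(4):  # intrapartum observations between admission and delivery
        day = adm + (k + 0.5) / 4.0 * (dlv - adm)
        parts.append(pd.DataFrame({"j": np.arange(n), "day": day, "kind": "intrapartum"}))

    for offset in (3.0, 14.0, 42.0):
        day = dlv + offset + rng.normal(0.0, config.visit_jitter_sd, n)
        keep = (rng.random(n) < config.postpartum_attendance) & (day < dlv + 69.0)
        parts.append(pd.DataFrame({"j": np.flatnonzero(keep), "day": day[keep],
                                   "kind": "postpartum"}))

    v = pd.concat(parts, ignore_index=True)
    v["day"] = v["day"] + rng.uniform(8.0, 17.0, len(v)) / 24.0 * (v["kind"] != "intrapartum")
    return v.sort_values(["j", "day"], kind="mergesort").reset_index(drop=True)


def _sbp_offset_at(day, sk_row_idx, sk, config):
    """Planted case offset: ramps in linearly over ``sbp_ramp_days`` before
    onset, full offset at and after onset, zero for controls."""
    onset = sk["onset"].to_numpy()[sk_row_idx]
    is_pe = sk["is_pe"].to_numpy()[sk_row_idx]
    frac = np.clip((day - (onset - config.sbp_ramp_days)) / config.sbp_ramp_days, 0.0, 1.0)
    frac = np.where(np.isnan(frac), 0.0, frac)
    return np.where(is_pe, config.pe_sbp_offset * frac, 0.0)


def generate_cohort(config: GeneratorConfig) -> RawEHR:
    """Generate the full synthetic cohort described by ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    sk = _journey_skeletons(config, rng)
    sk = assign_pe_scenarios(sk, config, rng)
    n = len(sk)
    n_female = config.n_patients - int(round(config.n_patients * config.male_fraction))
    n_male = config.n_patients - n_female
    patients = _make_patients(sk, n_female, n_male, config, rng)
    pid = patients["patient_id"].to_numpy()
    sk["patient_id"] = pid[sk["patient_idx"].to_numpy()]

    start = sk["start"].to_numpy()
    adm = sk["admission"].to_numpy()
    dlv = sk["delivery"].to_numpy()
    is_pe = sk["is_pe"].to_numpy()
    onset = sk["onset"].to_numpy()
    rule_ev = sk["rule_evidence"].to_numpy()
    icd = sk["icd_coded"].to_numpy()

    # per-journey disease severity: scales every planted case effect
    # (mean 1, so population-level effect sizes match the config)
    severity = rng.gamma(2.0, 0.5, size=n)
    sev_bp = 0.5 + 0.5 * severity  # blood pressure: milder heterogeneity

    visits = _visit_frame(sk, config, rng)
    vj = visits["j"].to_numpy()
    vday = visits["day"].to_numpy()
    vkind = visits["kind"].to_numpy()

    # ------------------------------------------------------------------ vitals
    pat_sbp_base = rng.normal(config.sbp_baseline_mean, 0.6 * config.sbp_baseline_sd, n_female)
    noise_sd = 0.8 * config.sbp_baseline_sd
    vit_parts = []

    def add_vitals(j_idx, day, vtype, value):
        vit_parts.append(pd.DataFrame({
            "j": j_idx, "type": vtype, "value": value, "day": day}))

    has_vitals = vkind != "baseline"
    hv_j, hv_day = vj[has_vitals], vday[has_vitals]
    p_of_j = sk["patient_idx"].to_numpy()
    offs = _sbp_offset_at(hv_day, hv_j, sk, config) * sev_bp[hv_j]
    sbp = pat_sbp_base[p_of_j[hv_j]] + offs + rng.normal(0, noise_sd, hv_j.size)
    add_vitals(hv_j, hv_day, "sbp", sbp)
    add_vitals(hv_j, hv_day, "dbp",
               67.0 + 0.5 * offs + 0.3 * (sbp - config.sbp_baseline_mean)
               + rng.normal(0, 5.0, hv_j.size))
    pat_pulse = rng.normal(0.0, 7.0, n)  # journey-level intercepts: biological
    add_vitals(hv_j, hv_day, "pulse",    # variation the repeated readings share
               80.0 + 4.0 * (is_pe * severity)[hv_j] + pat_pulse[hv_j]
               + rng.normal(0, 7.0, hv_j.size))
    add_vitals(hv_j, hv_day, "temperature", rng.normal(98.2, 0.5, hv_j.size))
    add_vitals(hv_j, hv_day, "o2_saturation",
               np.minimum(rng.normal(97.8, 1.0, hv_j.size), 100.0))
    add_vitals(hv_j, hv_day, "respirations", rng.normal(16.0, 2.0, hv_j.size))

    pat_weight = rng.normal(65.0, 12.0, n_female)
    gest_frac = np.clip((hv_day - start[hv_j]) / 280.0, 0.0, 1.1)
    add_vitals(hv_j, hv_day, "weight",
               pat_weight[p_of_j[hv_j]] + 3.0 * is_pe[hv_j] + 12.0 * gest_frac
               + rng.normal(0, 0.8, hv_j.size))

    base = vkind == "baseline"
    add_vitals(vj[base], vday[base], "weight",
               pat_weight[p_of_j[vj[base]]] + 3.0 * is_pe[vj[base]]
               + rng.normal(0, 0.8, base.sum()))
    add_vitals(vj[base], vday[base], "height", rng.normal(163.0, 7.0, base.sum()))
    add_vitals(vj[base], vday[base], "sbp",
               pat_sbp_base[p_of_j[vj[base]]] + rng.normal(0, noise_sd, base.sum()))
    add_vitals(vj[base], vday[base], "dbp", rng.normal(67.0, 5.0, base.sum()))

    intra = vkind == "intrapartum"
    add_vitals(vj[intra], vday[intra], "pain", rng.integers(2, 11, intra.sum()).astype(float))
    post = vkind == "postpartum"
    add_vitals(vj[post], vday[post], "pain", rng.integers(0, 7, post.sum()).astype(float))

    # planted rule-evidence episode: two high readings at onset, onset(+<=1d)
    ep_j = np.flatnonzero(rule_ev)
    for k, delta in enumerate((0.0, 1.0)):
        d = onset[ep_j] + delta * np.where(sk["subtype"].to_numpy()[ep_j] == "intrapartum",
                                           0.05, 1.0)
        add_vitals(ep_j, d, "sbp", rng.uniform(141.0, 158.0, ep_j.size))
        add_vitals(ep_j, d, "dbp", rng.uniform(86.0, 102.0, ep_j.size))

    vitals = pd.concat(vit_parts, ignore_index=True)
    # cases planted *without* rule evidence must stay below the rule
    # thresholds, or severe ambient trajectories would contradict the flag
    no_ev = is_pe & ~rule_ev
    jvals = vitals["j"].to_numpy()
    for vtype, cap in (("sbp", 137.0), ("dbp", 87.0)):
        m = no_ev[jvals] & (vitals["type"] == vtype).to_numpy()
        vitals.loc[m, "value"] = np.minimum(vitals.loc[m, "value"], cap)
    # planted data-entry errors, to exercise plausibility cleaning
    bad = (rng.random(len(vitals)) < config.implausible_rate) & (vitals["type"] != "pain")
    vitals.loc[bad, "value"] = vitals.loc[bad, "type"].map(_IMPLAUSIBLE).astype(float)
    vitals["value"] = np.round(vitals["value"].to_numpy(), 1)

    # -------------------------------------------------------------------- labs
    lab_parts = []
    lab_visits = has_vitals & (vkind != "intrapartum")
    lj, lday = vj[lab_visits], vday[lab_visits]
    gw = (lday - start[lj]) / 7.0

    urine_p = np.where(is_pe[lj][:, None], _URINE_P_PE, _URINE_P_CONTROL)
    cum = urine_p.cumsum(axis=1)
    draw = rng.random(lj.size)[:, None]
    urine_idx = (draw > cum).sum(axis=1)
    lab_parts.append(pd.DataFrame({
        "j": lj, "analyte": "urine_protein", "value_numeric": np.nan,
        "value_text": np.array(_ORDINAL_TEXT, object)[urine_idx], "unit": "ordinal",
        "day": lday}))

    def add_lab(j_idx, day, analyte, value, unit):
        lab_parts.append(pd.DataFrame({
            "j": j_idx, "analyte": analyte, "value_numeric": np.round(value, 2),
            "value_text": np.nan, "unit": unit, "day": day}))

    # journey-level random intercepts so repeated measurements share the
    # subject's own level and aggregates do not separate unrealistically
    ri = {name: rng.normal(0.0, sd, n) for name, sd in (
        ("fibrinogen", 28.0), ("mch", 1.8), ("wbc", 1.5), ("platelets", 42.0),
        ("hemoglobin", 0.8), ("uric_acid", 0.65))}
    pe_eff = is_pe * severity
    fib_slope = rng.normal(0.25, 0.08, n)  # physiologic rise varies by journey
    fib_rise = config.fibrinogen_rise_per_week * np.maximum(0.0, gw - 16.0) * pe_eff[lj]
    add_lab(lj, lday, "fibrinogen",
            350.0 + fib_slope[lj] * np.maximum(lday - start[lj], 0.0)
            + ri["fibrinogen"][lj] + rng.normal(0, 22.0, lj.size) + fib_rise, "mg/dL")
    add_lab(lj, lday, "mch", 30.0 + ri["mch"][lj] + rng.normal(0, 0.9, lj.size)
            + config.mch_offset * pe_eff[lj], "pg")
    add_lab(lj, lday, "wbc", 9.0 + ri["wbc"][lj] + rng.normal(0, 1.0, lj.size)
            + 0.8 * pe_eff[lj], "10^3/uL")
    add_lab(lj, lday, "platelets", 250.0 + ri["platelets"][lj]
            + rng.normal(0, 26.0, lj.size) - 15.0 * pe_eff[lj], "10^3/uL")
    add_lab(lj, lday, "hemoglobin", 12.5 + ri["hemoglobin"][lj]
            + rng.normal(0, 0.6, lj.size), "g/dL")
    add_lab(lj, lday, "uric_acid", 4.2 + ri["uric_acid"][lj]
            + rng.normal(0, 0.5, lj.size) + 0.4 * pe_eff[lj], "mg/dL")

    # planted proteinuria evidence near the episode anchor
    pe_text = np.array(("small", "moderate", "large"), object)
    lab_parts.append(pd.DataFrame({
        "j": ep_j, "analyte": "urine_protein", "value_numeric": np.nan,
        "value_text": pe_text[rng.choice(3, ep_j.size, p=(0.6, 0.3, 0.1))],
        "unit": "ordinal", "day": onset[ep_j] + rng.uniform(-1.0, 1.0, ep_j.size)}))
    labs = pd.concat(lab_parts, ignore_index=True)

    # --------------------------------------------------------- coded events
    dx_parts, rx_parts, pr_parts = [], [], []

    def add_dx(j_idx, day, code):
        dx_parts.append(pd.DataFrame({"j": j_idx, "code": code, "day": day}))

    def add_rx(j_idx, day, ingredient):
        rx_parts.append(pd.DataFrame({"j": j_idx, "ingredient": ingredient, "day": day}))

    def add_pr(j_idx, day, code):
        pr_parts.append(pd.DataFrame({"j": j_idx, "code": code, "day": day}))

    # chronic conditions recorded at the baseline encounter of every journey
    base_day = np.full(n, np.nan)
    base_day[vj[base]] = vday[base]
    for col, code in (("chronic_htn", "DX_CHTN"), ("diabetes", "DX_DM"),
                      ("renal_disease", "DX_RENAL"), ("autoimmune_disease", "DX_AUTOIMM")):
        flag = patients[col].to_numpy()[:n_female][p_of_j] == 1
        jj = np.flatnonzero(flag)
        add_dx(jj, base_day[jj], code)

    j_all = np.arange(n)
    u = rng.random(n)
    hd = u < np.where(is_pe, 0.15, 0.06)
    add_dx(j_all[hd], (start + rng.uniform(0.2, 0.9, n) * (adm - start))[hd], "DX_HEADACHE")
    nz = rng.random(n) < 0.30
    add_dx(j_all[nz], (start + rng.uniform(30, 90, n))[nz], "DX_NAUSEA")
    ur = rng.random(n) < 0.10
    add_dx(j_all[ur], (start + rng.uniform(-200, 260, n))[ur], "DX_URI")
    an = rng.random(n) < 0.08
    add_dx(j_all[an], (start + rng.uniform(60, 240, n))[an], "DX_ANEMIA")
    mf = rng.random(n) < np.where(is_pe, 0.045, 0.02)
    add_dx(j_all[mf], (start + rng.uniform(80, 95, n))[mf], "DX_MULTIFETAL")
    ghtn = is_pe & (rng.random(n) < 0.25) & ~np.isnan(onset)
    add_dx(j_all[ghtn], np.maximum(onset - 7.0, start + 142.0)[ghtn], "DX_GHTN")
    prom = rng.random(n) < 0.08
    add_dx(j_all[prom], adm[prom], "DX_PROM")
    dxdel = rng.random(n) < 0.70
    add_dx(j_all[dxdel], dlv[dxdel], "DX_DELIVERY")

    if icd.any():
        add_dx(j_all[icd], onset[icd], "DX_PE")
    protu_dx = rule_ev & (rng.random(n) < 0.30)
    add_dx(j_all[protu_dx], (onset + rng.uniform(-1, 1, n))[protu_dx], "DX_PROTU")

    pv = rng.random(n) < 0.80
    add_rx(j_all[pv], (start + rng.uniform(20, 60, n))[pv], "prenatal_vitamin")
    od = nz & (rng.random(n) < 0.5)
    add_rx(j_all[od], (start + rng.uniform(35, 95, n))[od], "ondansetron")
    chtn_j = patients["chronic_htn"].to_numpy()[:n_female][p_of_j] == 1
    lb = chtn_j & (rng.random(n) < 0.7)
    add_rx(j_all[lb], (start - rng.uniform(0, 200, n))[lb], "labetalol")
    lb2 = is_pe & (rng.random(n) < 0.4) & ~np.isnan(onset)
    add_rx(j_all[lb2], (onset + 0.5)[lb2], "labetalol")
    asp = (patients["prior_pe"].to_numpy()[:n_female][p_of_j] == 1) & (rng.random(n) < 0.7)
    add_rx(j_all[asp], (start + 84.0)[asp], "aspirin")
    oxy = rng.random(n) < 0.30
    add_rx(j_all[oxy], (adm + 1.5 / 24.0)[oxy], "oxytocin")
    ibu = rng.random(n) < np.where(is_pe, 0.30, 0.40)
    add_rx(j_all[ibu], (dlv + rng.uniform(0.2, 3.0, n))[ibu], "ibuprofen")

    cs = rng.random(n) < np.where(is_pe, 0.45, 0.28)
    add_pr(j_all[cs], dlv[cs], "PR_CESAREAN")
    add_pr(j_all[~cs], dlv[~cs], "PR_VAGINAL")
    ot = ~cs & (rng.random(n) < 0.5)
    add_dx(j_all[ot], (dlv + 0.5)[ot], "DX_OBTRAUMA")
    ep = rng.random(n) < 0.60
    add_pr(j_all[ep], (adm + 1.0 / 24.0)[ep], "PR_EPIDURAL")

    # ------------------------------------------------------------- admissions
    admissions = pd.DataFrame({
        "j": j_all, "facility": "MSH-LD",
        "admit": adm, "discharge": dlv + 1.5, "labor_and_delivery": 1})
    out_adm = rng.random(n) < 0.10
    admissions = pd.concat([admissions, pd.DataFrame({
        "j": j_all[out_adm], "facility": "MSH-CLINIC",
        "admit": (start + rng.uniform(10, 200, n))[out_adm],
        "discharge": (start + rng.uniform(10, 200, n))[out_adm] + 0.2,
        "labor_and_delivery": 0})], ignore_index=True)
    male_adm = pd.DataFrame({
        "j": -1, "facility": "MSH-CLINIC",
        "admit": rng.uniform(3000, 6000, n_male), "discharge": rng.uniform(3000, 6000, n_male),
        "labor_and_delivery": 0,
        "patient_id": patients["patient_id"].to_numpy()[n_female:]})

    # ------------------------------------------------------------- gw reports
    ante_v = vkind == "antepartum"
    rep = ante_v & (rng.random(len(visits)) < config.gw_report_rate)
    gw_reports = pd.DataFrame({
        "j": np.concatenate([vj[rep], j_all]),
        "day": np.concatenate([vday[rep], adm]),
        "gestational_week": np.concatenate([
            np.floor((vday[rep] - start[vj[rep]]) / 7.0),
            np.floor((adm - start) / 7.0)]).astype(int),
    })

    # ----------------------------------------------------------- final frames
    jpid = sk["patient_id"].to_numpy()

    def finalize(parts, datecol, rename=None):
        df = pd.concat(parts, ignore_index=True) if isinstance(parts, list) else parts
        df = df[~np.isnan(df["day"].to_numpy(float))].copy()
        df.insert(0, "patient_id", jpid[df.pop("j").to_numpy()])
        df[datecol] = _days_to_dt(df.pop("day").to_numpy())
        cols = ["patient_id"] + [c for c in df.columns if c != "patient_id"]
        df = df[cols].sort_values(["patient_id", datecol], kind="mergesort")
        return df.reset_index(drop=True)

    diagnoses = finalize(dx_parts, "date")
    medications = finalize(rx_parts, "date")
    procedures = finalize(pr_parts, "date")
    vitals_f = finalize(vitals, "datetime")
    vitals_f["unit"] = vitals_f["type"].map(_VITAL_UNITS)
    vitals_f = vitals_f[["patient_id", "type", "value", "unit", "datetime"]]
    labs_f = finalize(labs, "datetime")
    labs_f = labs_f[["patient_id", "analyte", "value_numeric", "value_text", "unit",
                     "datetime"]]
    gw_f = finalize(gw_reports, "report_date")
    gw_f = gw_f[["patient_id", "report_date", "gestational_week"]]

    admissions["patient_id"] = jpid[np.maximum(admissions["j"].to_numpy(), 0)]
    admissions = admissions.drop(columns="j")
    admissions = pd.concat([admissions, male_adm.drop(columns="j")], ignore_index=True)
    admissions["admit_datetime"] = _days_to_dt(admissions.pop("admit").to_numpy())
    admissions["discharge_datetime"] = _days_to_dt(admissions.pop("discharge").to_numpy())
    admissions = admissions[["patient_id", "facility", "admit_datetime",
                             "discharge_datetime", "labor_and_delivery"]]
    admissions = admissions.sort_values(["patient_id", "admit_datetime"],
                                        kind="mergesort").reset_index(drop=True)

    truth = pd.DataFrame({
        "patient_id": jpid,
        "pregnancy_start": _days_to_dt(start),
        "admission": _days_to_dt(adm),
        "delivery": _days_to_dt(dlv),
        "is_pe": is_pe.astype(int),
        "subtype": sk["subtype"],
        "onset": _days_to_dt(np.where(np.isnan(onset), np.nan, onset)),
        "icd_coded": icd.astype(int),
        "rule_evidence": rule_ev.astype(int),
    })

    return RawEHR(patients=patients.drop(columns=["chronic_htn", "diabetes", "renal_disease",
                                                  "autoimmune_disease"]),
                  admissions=admissions, diagnoses=diagnoses, medications=medications,
                  procedures=procedures, vitals=vitals_f, labs=labs_f, gw_reports=gw_f,
                  truth=truth)


# --------------------------------------------------------------------- I/O

_SUPPORTED_FORMATS = ("csv", "parquet")

_DATE_COLS = {
    "patients": ["birth_date"],
    "admissions": ["admit_datetime", "discharge_datetime"],
    "diagnoses": ["date"], "medications": ["date"], "procedures": ["date"],
    "vitals": ["datetime"], "labs": ["datetime"], "gw_reports": ["report_date"],
    "truth": ["pregnancy_start", "admission", "delivery", "onset"],
}


def emit_tables(ehr: RawEHR, out_dir: str | Path, format: str = "csv") -> pd.DataFrame:
    """Write one file per table; returns a manifest (table, path, n_rows)."""
    if format not in _SUPPORTED_FORMATS:
        raise ConfigurationError(
            f"unknown format {format!r}; supported: {', '.join(_SUPPORTED_FORMATS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, df in ehr.tables().items():
        path = out / f"{name}.{format}"
        if format == "csv":
            df.to_csv(path, index=False)
        else:
            df.to_parquet(path, index=False)
        rows.append({"table": name, "path": str(path), "n_rows": len(df)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_tables(in_dir: str | Path, format: str = "csv") -> RawEHR:
    """Re-read tables written by :func:`emit_tables` (round-trip identity)."""
    if format not in _SUPPORTED_FORMATS:
        raise ConfigurationError(
            f"unknown format {format!r}; supported: {', '.join(_SUPPORTED_FORMATS)}")
    in_dir = Path(in_dir)
    frames = {}
    for name in TABLE_NAMES:
        path = in_dir / f"{name}.{format}"
        if format == "csv":
            df = pd.read_csv(path)
            for c in _DATE_COLS[name]:
                df[c] = pd.to_datetime(df[c])
            if name == "labs" and len(df) == 0:
                df["value_text"] = df["value_text"].astype(object)
        else:
            df = pd.read_parquet(path)
        frames[name] = df
    return RawEHR(**frames)
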