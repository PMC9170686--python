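"""Shared fixtures: small synthetic cohorts and the brute-force labelling
oracle used to cross-check the production phenotyper."""

import numpy as np
import pandas as pd
import pytest

from petimeline import (CodeSets, GeneratorConfig, PhenotypeConfig, build_journeys,
                        generate_cohort, phenotype_journeys)
from petimeline.features import encode_lab_ordinal_series, clean_vitals


@pytest.fixture(scope="session")
def small_cohort():
    """~500 journeys; shared read-only across tests."""
    ehr = generate_cohort(GeneratorConfig(n_patients=400, seed=7))
    journeys = build_journeys(ehr)
    labels = phenotype_journeys(ehr, journeys)
    return ehr, journeys, labels


@pytest.fixture(scope="session")
def mid_cohort():
    """~1500 journeys for model-level checks."""
    ehr = generate_cohort(GeneratorConfig(n_patients=1200, seed=2))
    journeys = build_journeys(ehr)
    labels = phenotype_journeys(ehr, journeys)
    return ehr, journeys, labels


def brute_force_labels(ehr, journeys: pd.DataFrame,
                       code_sets: CodeSets | None = None,
                       config: PhenotypeConfig | None = None) -> pd.DataFrame:
    """Independent oracle: per journey, scan all reading pairs and all
    evidence events directly (O(n^2)), no shared code path with the
    vectorized phenotyper beyond input cleaning."""
    code_sets = code_sets or CodeSets()
    config = config or PhenotypeConfig()
    vit = clean_vitals(ehr.vitals)
    rows = []
    for _, j in journeys.iterrows():
        pid = j["patient_id"]
        w0, w1 = j["window_start"], j["window_end"]
        gw20 = j["pregnancy_start"] + pd.Timedelta(days=7 * config.onset_min_gestational_week)

        def in_window(t):
            return (t >= w0) & (t <= w1)

        dx = ehr.diagnoses[(ehr.diagnoses["patient_id"] == pid)
                           & in_window(ehr.diagnoses["date"])]
        pe_dates = sorted(dx.loc[dx["code"].isin(code_sets.pe_diagnosis), "date"])
        pe_dates = [d for d in pe_dates if gw20 <= d <= w1]
        icd_onset = pe_dates[0] if pe_dates else None

        v = vit[(vit["patient_id"] == pid) & in_window(vit["datetime"])]
        high = v[((v["type"] == "sbp") & (v["value"] >= config.sbp_threshold)) |
                 ((v["type"] == "dbp") & (v["value"] >= config.dbp_threshold))]
        times = sorted({t for t in high["datetime"] if gw20 <= t <= w1})
        anchor = None
        for a in range(len(times)):           # all pairs, earliest first
            for b in range(len(times)):
                if a == b:
                    continue
                if abs((times[b] - times[a]).total_seconds()) <= \
                        config.pair_window_days * 86400 and times[a] <= times[b]:
                    anchor = times[a]
                    break
            if anchor is not None:
                break

        rule_fire = False
        if anchor is not None:
            evid = list(dx.loc[dx["code"].isin(code_sets.proteinuria_diagnosis), "date"])
            labs = ehr.labs[(ehr.labs["patient_id"] == pid)
                            & in_window(ehr.labs["datetime"])]
            urine = labs[labs["analyte"].isin(code_sets.urine_protein_analytes)]
            ords = encode_lab_ordinal_series(urine["value_text"])
            nums = pd.to_numeric(urine["value_numeric"], errors="coerce")
            hit = ((ords >= config.ordinal_threshold) |
                   (nums >= config.quantitative_threshold)).fillna(False)
            evid += list(urine.loc[hit.to_numpy(), "datetime"])
            rule_fire = any(abs((e - anchor).total_seconds())
                            <= config.evidence_window_days * 86400 for e in evid)

        is_pe = icd_onset is not None or rule_fire
        onset = icd_onset if icd_onset is not None else (anchor if rule_fire else None)
        if not is_pe:
            subtype, source = "none", "none"
        else:
            source = ("both" if icd_onset is not None and rule_fire
                      else "icd" if icd_onset is not None else "rule")
            if onset < j["admission"]:
                subtype = "antepartum"
            elif onset <= j["delivery"]:
                subtype = "intrapartum"
            else:
                subtype = "postpartum"
        rows.append({"journey_id": j["journey_id"], "is_pe": is_pe,
                     "onset": onset if is_pe else pd.NaT, "subtype": subtype,
                     "source": source})
    return pd.DataFrame(rows)


def make_rng_matrix(n=2000, p=8, informative=(0,), beta=1.0, seed=0,
                    base_rate=0.1):
    """Tiny logistic simulation used by selection / OR recovery tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    logit = np.log(base_rate / (1 - base_rate)) + sum(
        beta * X[:, i] for i in informative)
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    return X, y.astype(int)
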