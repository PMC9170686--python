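"""Shared configuration objects: generator settings, code vocabularies,
plausibility bounds and the ordinal lab vocabulary.

Everything here is plain data so runs are reproducible from a config file
alone.  Code vocabularies are synthetic stand-ins for ICD/CPT/RxNorm
concepts, grouped the way a CCS-style crosswalk would group them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its contract."""


#: Ordinal encoding of descriptive (dipstick-style) lab text.
ORDINAL_VOCAB: dict[str, int] = {
    "negative": 1,
    "trace": 2,
    "small": 3,
    "moderate": 4,
    "large": 5,
}

#: Vital-sign plausibility bounds (values outside are physically impossible
#: for a living patient and treated as data-entry errors).  Pain scores are
#: exempt from range removal.
VITAL_BOUNDS: dict[str, tuple[float, float]] = {
    "sbp": (40.0, 370.0),
    "dbp": (20.0, 360.0),
    "pulse": (20.0, 300.0),
    "temperature": (70.0, 115.0),
    "weight": (20.0, 727.0),
    "height": (50.0, 272.0),
    "o2_saturation": (50.0, 100.0),
    "respirations": (4.0, 120.0),
}

#: Vital types eligible for sparse FPCA by default.
FPCA_VITALS: tuple[str, ...] = (
    "dbp", "sbp", "o2_saturation", "pulse", "respirations", "temperature", "weight",
)

#: Numeric lab analytes eligible for sparse FPCA by default.
FPCA_LABS: tuple[str, ...] = ("fibrinogen", "mch", "wbc", "platelets")


# ---------------------------------------------------------------------------
# Synthetic code vocabulary.  Codes look like ICD/CPT/ingredient tokens but
# are invented; `group` is the CCS-style category used for features.
# ---------------------------------------------------------------------------

DIAGNOSIS_GROUPS: dict[str, str] = {
    "DX_PE": "preeclampsia",
    "DX_GHTN": "gestational_hypertension",
    "DX_CHTN": "chronic_hypertension",
    "DX_PROTU": "proteinuria",
    "DX_HEADACHE": "headache",
    "DX_DM": "diabetes",
    "DX_RENAL": "renal_disease",
    "DX_AUTOIMM": "autoimmune_disease",
    "DX_MULTIFETAL": "multifetal_gestation",
    "DX_NAUSEA": "nausea",
    "DX_URI": "upper_resp_infection",
    "DX_ANEMIA": "anemia",
    "DX_OBTRAUMA": "ob_trauma",
    "DX_DELIVERY": "delivery",
    "DX_PROM": "prom",
}

MEDICATION_GROUPS: dict[str, str] = {
    "prenatal_vitamin": "prenatal_vitamin",
    "labetalol": "labetalol",
    "aspirin": "aspirin",
    "oxytocin": "oxytocin",
    "ibuprofen": "ibuprofen",
    "ondansetron": "ondansetron",
}

PROCEDURE_GROUPS: dict[str, str] = {
    "PR_CESAREAN": "cesarean_delivery",
    "PR_VAGINAL": "vaginal_delivery",
    "PR_EPIDURAL": "epidural_anesthesia",
    "PR_GENANESTH": "general_anesthesia",
}


@dataclass(frozen=True)
class CodeSets:
    """Code vocabularies driving journey construction and phenotyping."""

    pe_diagnosis: frozenset[str] = frozenset({"DX_PE"})
    proteinuria_diagnosis: frozenset[str] = frozenset({"DX_PROTU"})
    delivery_diagnosis: frozenset[str] = frozenset({"DX_DELIVERY"})
    cesarean_procedures: frozenset[str] = frozenset({"PR_CESAREAN"})
    vaginal_procedures: frozenset[str] = frozenset({"PR_VAGINAL"})
    urine_protein_analytes: frozenset[str] = frozenset({"urine_protein"})
    diagnosis_groups: dict[str, str] = field(default_factory=lambda: dict(DIAGNOSIS_GROUPS))
    medication_groups: dict[str, str] = field(default_factory=lambda: dict(MEDICATION_GROUPS))
    procedure_groups: dict[str, str] = field(default_factory=lambda: dict(PROCEDURE_GROUPS))


@dataclass(frozen=True)
class PhenotypeConfig:
    """Rule thresholds for the digital preeclampsia phenotype."""

    sbp_threshold: float = 140.0
    dbp_threshold: float = 90.0
    pair_window_days: float = 3.0        # two high readings within this window
    evidence_window_days: float = 3.0    # proteinuria evidence around the anchor
    ordinal_threshold: int = 3           # "small" and above counts as proteinuria
    quantitative_threshold: float = 300.0  # mg/24h, ACOG
    onset_min_gestational_week: int = 20
    postpartum_days: int = 70


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic EMR cohort.

    Defaults encode the cohort the analysis assumes: ~9.3% preeclampsia
    prevalence split into ante/intra/postpartum subtypes, 1.29 pregnancy
    journeys per patient, ~273-day journeys, systolic blood pressure in
    cases elevated ~10 mmHg but usually still in the normal range, and
    only a minority of cases carrying an explicit diagnosis code — of
    which ~91.36% also carry rule evidence.
    """

    n_patients: int = 1000
    journeys_per_patient_mean: float = 1.29
    pe_prevalence: float = 0.093
    subtype_weights: tuple[float, float, float] = (0.020, 0.062, 0.011)
    icd_coding_rate: float = 0.30
    rule_evidence_rate_given_icd: float = 0.9136
    sbp_baseline_mean: float = 110.0
    sbp_baseline_sd: float = 8.0
    pe_sbp_offset: float = 10.0
    sbp_ramp_days: int = 42              # offset ramps in over 6 weeks pre-onset
    journey_length_mean: float = 273.0
    journey_length_sd: float = 8.0
    visit_jitter_sd: float = 2.0
    visit_attendance: float = 0.85       # per-protocol-visit attendance prob
    postpartum_attendance: float = 0.70
    gw_report_rate: float = 0.5          # prob a visit files a gestational-week report
    mch_offset: float = -1.0             # cases run ~1 pg lower in MCH
    fibrinogen_rise_per_week: float = 2.0  # extra mg/dL per week past week 16 in cases
    implausible_rate: float = 0.002      # data-entry errors planted to exercise cleaning
    male_fraction: float = 0.02          # non-eligible patients to exercise cohort filters
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for name in ("pe_prevalence", "icd_coding_rate", "rule_evidence_rate_given_icd",
                     "visit_attendance", "postpartum_attendance", "gw_report_rate",
                     "implausible_rate", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.pe_prevalence >= 1.0:
            raise ConfigurationError("pe_prevalence must be < 1")
        if any(w < 0 for w in self.subtype_weights):
            raise ConfigurationError("subtype weights must be non-negative")
        if sum(self.subtype_weights) > 1.0:
            raise ConfigurationError("subtype weights must sum to <= 1")
        if self.journeys_per_patient_mean < 1.0:
            raise ConfigurationError("journeys_per_patient_mean must be >= 1")

    def normalized_subtype_weights(self) -> tuple[float, float, float]:
        """Weights rescaled to sum to ``pe_prevalence`` (their conditional
        split is what matters; absolute level is carried by prevalence)."""
        total = sum(self.subtype_weights)
        if total == 0:
            return (0.0, 0.0, 0.0) if self.pe_prevalence == 0 else (1 / 3,) * 3
        return tuple(w / total for w in self.subtype_weights)  # type: ignore[return-value]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "subtype_weights" in d:
            d["subtype_weights"] = tuple(d["subtype_weights"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


#: High/moderate clinical risk factors for the guideline comparator score.
ACOG_HIGH_FACTORS: tuple[str, ...] = (
    "history_of_preeclampsia",
    "multifetal_gestation",
    "chronic_hypertension",
    "diabetes",
    "renal_disease",
    "autoimmune_disease",
)
ACOG_MODERATE_FACTORS: tuple[str, ...] = (
    "nulliparity",
    "obesity",
    "family_history_preeclampsia",
    "sociodemographic",
    "age_35_or_older",
    "personal_history_factors",
)
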