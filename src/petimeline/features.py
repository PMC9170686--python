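"""Per-time-point feature engineering.

The prenatal protocol defines 19 time points: 17 antepartum visits
(monthly weeks 4-20, biweekly weeks 22-34, weekly weeks 35-39) plus
intrapartum and postpartum.  For each time point a feature matrix is built
from events up to that point's cutoff only:

* demographics and baseline history;
* first-timing features (gestational week of the first event in each
  diagnosis / medication-ingredient / procedure group; absent events are
  missing here and zero-filled only inside the selector's sparse track);
* per-period (ante/intra/postpartum) minimum / median / maximum of numeric
  vitals and labs, maximum-only for pain scores and for ordinal-encoded
  descriptive labs;
* sparse-FPCA component scores of longitudinal vitals and labs (subjects
  need more than 3 observations to be scored);
* delivery-mode indicators, only at the intrapartum point and later.

Missingness is explicit (NaN) and never imputed — downstream learners
route missing values natively.  Journeys whose case onset precedes the
prediction target of a time point are excluded from that matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (CodeSets, FPCA_LABS, FPCA_VITALS, ORDINAL_VOCAB, VITAL_BOUNDS)
from .fpca import SparseFPCA

logger = logging.getLogger(__name__)

ANTEPARTUM_WEEKS = (4, 8, 12, 16, 20, 22, 24, 26, 28, 30, 32, 34, 35, 36, 37, 38, 39)


@dataclass(frozen=True)
class TimePoint:
    index: int                 # 1..19
    kind: str                  # gestational_week | intrapartum | postpartum
    week: int | None = None

    @property
    def name(self) -> str:
        return f"week_{self.week}" if self.kind == "gestational_week" else self.kind


def build_timepoint_schedule() -> list[TimePoint]:
    """The 19 protocol time points, in order."""
    tps = [TimePoint(i + 1, "gestational_week", w) for i, w in enumerate(ANTEPARTUM_WEEKS)]
    tps.append(TimePoint(18, "intrapartum"))
    tps.append(TimePoint(19, "postpartum"))
    return tps


def encode_lab_ordinal(text) -> float:
    """Map descriptive dipstick text to its ordinal (negative=1 .. large=5);
    unmapped text becomes missing."""
    if not isinstance(text, str):
        return np.nan
    v = ORDINAL_VOCAB.get(text.strip().lower())
    if v is None:
        logger.debug("unmapped descriptive lab value %r", text)
        return np.nan
    return float(v)


def encode_lab_ordinal_series(s) -> pd.Series:
    if s is None:
        return pd.Series(dtype=float)
    return pd.Series(
        s.astype("string").str.strip().str.lower().map(ORDINAL_VOCAB).astype(float),
        index=s.index)


def clean_vitals(vitals: pd.DataFrame,
                 bounds: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Drop vital values outside plausibility bounds (pain scores exempt;
    unknown vital types pass through with a warning)."""
    bounds = bounds if bounds is not None else VITAL_BOUNDS
    known = vitals["type"].isin(bounds) | (vitals["type"] == "pain")
    if (~known).any():
        logger.warning("unknown vital types pass through uncleaned: %s",
                       sorted(vitals.loc[~known, "type"].unique()))
    lo = vitals["type"].map({k: v[0] for k, v in bounds.items()})
    hi = vitals["type"].map({k: v[1] for k, v in bounds.items()})
    ok = lo.isna() | ((vitals["value"] >= lo) & (vitals["value"] <= hi))
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("plausibility filter removed %d vital readings", n_drop)
    return vitals[ok]


def summarize_period(values) -> tuple[float, float, float]:
    """(min, median, max) of the observations; all-NaN when empty."""
    arr = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce").dropna(), float)
    if arr.size == 0:
        return (np.nan, np.nan, np.nan)
    return (float(arr.min()), float(np.median(arr)), float(arr.max()))


def first_timing_week(first_date, pregnancy_start) -> float:
    """Gestational week (floored) of the first event; negative before
    pregnancy."""
    days = (pd.Timestamp(first_date) - pd.Timestamp(pregnancy_start)).days
    return float(np.floor(days / 7.0))


@dataclass
class FeaturizerConfig:
    fpca_vitals: tuple[str, ...] = FPCA_VITALS
    fpca_labs: tuple[str, ...] = FPCA_LABS
    fpca_components: int = 10
    fpca_min_obs: int = 4          # strictly more than 3 observations
    fpca_enabled: bool = True
    fpca_domain: tuple[float, float] = (0.0, 290.0)  # gestational days
    vital_bounds: dict = field(default_factory=lambda: dict(VITAL_BOUNDS))
    drop_empty_columns: bool = False  # keep the cutoff-determined dictionary


@dataclass
class FeatureMatrix:
    """Journeys x features at one time point, with explicit missingness."""

    timepoint: TimePoint
    X: pd.DataFrame                # index: journey_id
    y: pd.Series                   # case/control labels
    patient_ids: pd.Series         # for grouped cross-subject validation
    meta: pd.DataFrame             # feature -> category (+ period/transform)

    def categories(self) -> pd.Series:
        return self.meta.set_index("feature")["category"]


_PERIODS_FOR_KIND = {
    "gestational_week": ("ante",),
    "intrapartum": ("ante", "intra"),
    "postpartum": ("ante", "intra", "post"),
}


class FeatureBuilder:
    """Precomputes journey-linked event tables once, then builds the
    feature matrix for any time point."""

    def __init__(self, ehr, journeys: pd.DataFrame, labels: pd.DataFrame,
                 code_sets: CodeSets | None = None,
                 config: FeaturizerConfig | None = None):
        self.code_sets = code_sets or CodeSets()
        self.config = config or FeaturizerConfig()
        self.jn = journeys.reset_index(drop=True).set_index("journey_id", drop=False)
        self.labels = labels.set_index("journey_id").reindex(self.jn.index)
        self.ehr = ehr
        self._prepare(ehr)

    # ------------------------------------------------------------ preparation
    def _merge(self, df: pd.DataFrame, timecol: str) -> pd.DataFrame:
        j = self.jn[["journey_id", "patient_id", "window_start", "window_end",
                     "pregnancy_start", "admission", "delivery"]]
        m = df.merge(j, on="patient_id", how="inner", suffixes=("", "_j"))
        m = m[(m[timecol] >= m["window_start"]) & (m[timecol] <= m["window_end"])].copy()
        m["t"] = m[timecol]
        m["day"] = (m["t"] - m["pregnancy_start"]).dt.total_seconds() / 86400.0
        m["period"] = np.select(
            [m["t"] < m["admission"], m["t"] <= m["delivery"]],
            ["ante", "intra"], default="post")
        return m.drop(columns=["window_start", "window_end", "pregnancy_start",
                               "admission", "delivery"])

    def _prepare(self, ehr) -> None:
        cs = self.code_sets
        self.vitals = self._merge(clean_vitals(ehr.vitals, self.config.vital_bounds),
                                  "datetime")
        labs = self._merge(ehr.labs, "datetime")
        labs["ordinal"] = encode_lab_ordinal_series(labs["value_text"])
        labs["numeric"] = pd.to_numeric(labs["value_numeric"], errors="coerce")
        self.labs = labs

        dx = ehr.diagnoses[~ehr.diagnoses["code"].isin(cs.pe_diagnosis)].copy()
        dx["group"] = dx["code"].map(cs.diagnosis_groups)
        dx = dx[dx["group"].notna()]
        self.dx = self._merge(dx, "date")

        rx = ehr.medications.copy()
        rx["group"] = rx["ingredient"].map(cs.medication_groups).fillna(rx["ingredient"])
        self.rx = self._merge(rx, "date")

        pr = ehr.procedures.copy()
        pr["group"] = pr["code"].map(cs.procedure_groups)
        pr = pr[pr["group"].notna()]
        self.pr = self._merge(pr, "date")

        self.patients = ehr.patients.set_index("patient_id")

    # ---------------------------------------------------------------- cutoffs
    def cutoff(self, tp: TimePoint) -> pd.Series:
        """Per-journey event-inclusion cutoff datetime for a time point."""
        if tp.kind == "gestational_week":
            return self.jn["pregnancy_start"] + pd.Timedelta(days=7 * tp.week)
        if tp.kind == "intrapartum":
            return self.jn["delivery"]
        return self.jn["window_end"]

    def included_journeys(self, tp: TimePoint) -> pd.Index:
        """Journeys still at risk at this time point (cases with earlier
        onset are excluded)."""
        lab = self.labels
        if tp.kind == "gestational_week":
            cut = self.cutoff(tp)
            early = lab["is_pe"].fillna(False) & (lab["onset"] < cut)
        elif tp.kind == "intrapartum":
            early = lab["is_pe"].fillna(False) & (lab["onset"] < self.jn["admission"])
        else:
            early = lab["is_pe"].fillna(False) & (lab["onset"] <= self.jn["delivery"])
        return self.jn.index[~early.to_numpy(bool)]

    # --------------------------------------------------------------- builders
    def _clip(self, ev: pd.DataFrame, tp: TimePoint) -> pd.DataFrame:
        """Events at or before the time point's cutoff (all journeys; the
        feature dictionary is cutoff-determined, so columns never disappear
        when case rows are excluded later in the timeline)."""
        cut = self.cutoff(tp)
        keep = ev["t"].to_numpy() <= cut.loc[ev["journey_id"]].to_numpy()
        return ev[keep]

    def _demographics(self, ids: pd.Index) -> tuple[pd.DataFrame, list]:
        jn = self.jn.loc[ids]
        pat = self.patients.loc[jn["patient_id"]]
        X = pd.DataFrame(index=ids)
        X["demo__age"] = ((jn["pregnancy_start"].to_numpy()
                           - pat["birth_date"].to_numpy())
                          / np.timedelta64(1, "D") / 365.25)
        races = pat["race"].astype(str).str.split(";")
        vocab = sorted({r for rs in races for r in rs})
        for r in vocab:
            X[f"demo__race__{r}"] = races.apply(lambda rs: float(r in rs)).to_numpy()
        for col in ("medicaid", "smoking_history", "alcohol_history", "parity",
                    "prior_pe", "family_history_pe", "personal_history_factors"):
            X[f"demo__{col}"] = pat[col].to_numpy(float)
        meta = [{"feature": c, "category": "demographics"} for c in X.columns]
        return X, meta

    def _first_timing(self, ev: pd.DataFrame, prefix: str, category: str,
                      ids: pd.Index) -> tuple[pd.DataFrame, list]:
        if not len(ev):
            return pd.DataFrame(index=ids), []
        first = ev.groupby(["journey_id", "group"])["day"].min().unstack("group")
        wide = np.floor(first / 7.0)
        wide = wide.reindex(ids)
        wide.columns = [f"{prefix}__{g}" for g in wide.columns]
        meta = [{"feature": c, "category": category, "transform": "first_gw"}
                for c in wide.columns]
        return wide, meta

    def _aggregates(self, ev: pd.DataFrame, value_col: str, kindcol: str, prefix: str,
                    category: str, periods: tuple, ids: pd.Index,
                    max_only_kinds: tuple = ()) -> tuple[pd.DataFrame, list]:
        ev = ev[ev["period"].isin(periods)]
        if not len(ev):
            return pd.DataFrame(index=ids), []
        g = ev.groupby(["journey_id", kindcol, "period"])[value_col]
        agg = g.agg(["min", "median", "max"])
        agg = agg.unstack([kindcol, "period"])
        cols, meta = {}, []
        for stat, kind, period in agg.columns:
            if kind in max_only_kinds and stat != "max":
                continue
            name = f"{prefix}__{kind}__{period}__{stat}"
            cols[name] = agg[(stat, kind, period)]
            meta.append({"feature": name, "category": category, "period": period,
                         "transform": stat})
        X = pd.DataFrame(cols, index=agg.index).reindex(ids)
        return X, meta

    def _fpca_features(self, tp: TimePoint, ids: pd.Index,
                       train_ids: pd.Index | None,
                       bases: dict | None) -> tuple[pd.DataFrame, list, dict]:
        cfg = self.config
        X = pd.DataFrame(index=ids)
        meta, fitted = [], {}
        if not cfg.fpca_enabled:
            return X, meta, fitted
        signals = ([("vital", self.vitals, "type", "value", s) for s in cfg.fpca_vitals]
                   + [("lab", self.labs, "analyte", "numeric", s) for s in cfg.fpca_labs])
        for category, ev, kindcol, valcol, sig in signals:
            obs = ev[(ev[kindcol] == sig) & (ev["period"] == "ante")
                     & (ev["day"] >= cfg.fpca_domain[0])]
            obs = self._clip(obs, tp)
            if not len(obs):
                continue
            key = (category, sig)
            model = (bases or {}).get(key)
            try:
                if model is None:
                    model = SparseFPCA(n_components=cfg.fpca_components,
                                       min_obs=cfg.fpca_min_obs, domain=cfg.fpca_domain)
                    fit_obs = obs
                    if train_ids is not None:
                        fit_obs = obs[obs["journey_id"].isin(train_ids)]
                    model.fit(fit_obs["journey_id"].to_numpy(),
                              fit_obs["day"].to_numpy(), fit_obs[valcol].to_numpy())
                scores = model.score(obs["journey_id"].to_numpy(),
                                     obs["day"].to_numpy(), obs[valcol].to_numpy(),
                                     index=ids.to_numpy())
            except Exception as exc:  # degenerate signal at an early cutoff
                logger.info("FPCA skipped for %s at %s: %s", sig, tp.name, exc)
                continue
            fitted[key] = model
            scores.index = ids
            for c in scores.columns:
                name = f"fpca__{sig}__{c}"
                X[name] = scores[c]
                meta.append({"feature": name, "category": category,
                             "transform": "fpca"})
        return X, meta, fitted

    def matrix(self, tp: TimePoint, train_ids: pd.Index | None = None,
               fpca_bases: dict | None = None,
               return_bases: bool = False):
        """Assemble the feature matrix for one time point.

        ``train_ids`` restricts FPCA basis fitting to those journeys
        (scores are still produced for every included journey);
        ``fpca_bases`` reuses already-fitted bases instead.
        """
        ids = self.included_journeys(tp)
        periods = _PERIODS_FOR_KIND[tp.kind]
        blocks, meta = [], []

        Xd, md = self._demographics(ids)
        blocks.append(Xd); meta.extend(md)

        for ev, prefix, category in ((self.dx, "dx_gw", "diagnosis"),
                                     (self.rx, "rx_gw", "medication"),
                                     (self.pr, "pr_gw", "procedure")):
            sub = self._clip(ev, tp)
            Xb, mb = self._first_timing(sub, prefix, category, ids)
            blocks.append(Xb); meta.extend(mb)

        vit = self._clip(self.vitals, tp)
        Xv, mv = self._aggregates(vit, "value", "type", "vital", "vital",
                                  periods, ids, max_only_kinds=("pain",))
        blocks.append(Xv); meta.extend(mv)

        lab = self._clip(self.labs, tp)
        Xl, ml = self._aggregates(lab[lab["numeric"].notna()], "numeric", "analyte",
                                  "lab", "lab", periods, ids)
        blocks.append(Xl); meta.extend(ml)
        Xo, mo = self._aggregates(lab[lab["ordinal"].notna()], "ordinal", "analyte",
                                  "lab_ord", "lab", periods, ids,
                                  max_only_kinds=tuple(lab["analyte"].unique()))
        blocks.append(Xo); meta.extend(mo)

        Xf, mf, fitted = self._fpca_features(tp, ids, train_ids, fpca_bases)
        blocks.append(Xf); meta.extend(mf)

        if tp.kind in ("intrapartum", "postpartum"):
            mode = self.jn.loc[ids, "mode"]
            Xm = pd.DataFrame({
                "delivery__cesarean": (mode == "cesarean").astype(float),
                "delivery__vaginal": (mode == "vaginal").astype(float)}, index=ids)
            blocks.append(Xm)
            meta.extend([{"feature": c, "category": "procedure"} for c in Xm.columns])

        X = pd.concat(blocks, axis=1)
        if self.config.drop_empty_columns:
            keep = X.columns[X.notna().any(axis=0)]
            X = X[keep]
            meta = [m for m in meta if m["feature"] in set(keep)]

        y = self.labels.loc[ids, "is_pe"].astype(bool)
        fm = FeatureMatrix(timepoint=tp, X=X, y=y,
                           patient_ids=self.jn.loc[ids, "patient_id"],
                           meta=pd.DataFrame(meta))
        if return_bases:
            return fm, fitted
        return fm


def assemble_feature_matrix(ehr, journeys: pd.DataFrame, labels: pd.DataFrame,
                            timepoint: TimePoint,
                            code_sets: CodeSets | None = None,
                            config: FeaturizerConfig | None = None) -> FeatureMatrix:
    """One-shot matrix assembly; use :class:`FeatureBuilder` when building
    several time points from the same cohort."""
    return FeatureBuilder(ehr, journeys, labels, code_sets, config).matrix(timepoint)
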