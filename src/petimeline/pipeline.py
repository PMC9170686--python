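"""End-to-end study orchestration.

``TimelineStudy`` wires the stages together for a cohort: journey
reconstruction, case labelling, per-time-point featurization, four-method
feature selection, grouped cross-subject model fitting, and the guideline
comparator.  Its ``run()`` yields a :class:`StudyResults` with one
:class:`~petimeline.model.TimepointResults` per protocol time point and a
cross-time-point summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .acog import acog_auc_bootstrap, acog_factors_from_cohort, acog_risk_score
from .config import CodeSets, GeneratorConfig, PhenotypeConfig
from .features import FeatureBuilder, FeaturizerConfig, TimePoint, build_timepoint_schedule
from .journeys import JourneyConfig, build_journeys
from .model import TimepointModel
from .phenotype import phenotype_journeys
from .selection import SelectionConfig, select_features
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class StudyResults:
    per_timepoint: dict = field(default_factory=dict)  # name -> dict
    acog: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Median held-out metrics per time point."""
        rows = []
        for name, entry in self.per_timepoint.items():
            res = entry["results"]
            s = res.summary()
            rows.append({
                "timepoint": name,
                "n": len(res.model.y),
                "prevalence": float(res.model.y.mean()),
                "n_selected": len(entry["selected"]),
                **{f"{m}_median": s.loc[m, "median"] for m in s.index},
                **{f"{m}_q1": s.loc[m, "q1"] for m in s.index},
                **{f"{m}_q3": s.loc[m, "q3"] for m in s.index},
            })
        return pd.DataFrame(rows)


class TimelineStudy:
    """Fit timeline case-risk models for a reconstructed cohort."""

    def __init__(self, ehr, journeys=None, labels=None,
                 code_sets: CodeSets | None = None,
                 journey_config: JourneyConfig | None = None,
                 phenotype_config: PhenotypeConfig | None = None,
                 featurizer_config: FeaturizerConfig | None = None,
                 selection_config: SelectionConfig | None = None):
        self.ehr = ehr
        self.code_sets = code_sets or CodeSets()
        self.selection_config = selection_config or SelectionConfig()
        if journeys is None:
            journeys = build_journeys(ehr, self.code_sets, journey_config)
        self.journeys = journeys
        if labels is None:
            labels = phenotype_journeys(ehr, journeys, self.code_sets, phenotype_config)
        self.labels = labels
        self.builder = FeatureBuilder(ehr, journeys, labels, self.code_sets,
                                      featurizer_config)

    @classmethod
    def from_synthetic(cls, config: GeneratorConfig | None = None, **kwargs) -> "TimelineStudy":
        ehr = generate_cohort(config or GeneratorConfig())
        return cls(ehr, **kwargs)

    def feature_matrix(self, tp: TimePoint, **kwargs):
        return self.builder.matrix(tp, **kwargs)

    def run(self, timepoints: list[TimePoint] | None = None, k: int = 10,
            seed: int = 0, tune_evals: int = 0, select: bool = True,
            force_include: list[str] | None = None,
            run_acog: bool = True, acog_reps: int = 1000) -> StudyResults:
        """Featurize, select, fit and evaluate at each requested time point."""
        tps = timepoints or build_timepoint_schedule()
        out = StudyResults()
        for tp in tps:
            fm = self.builder.matrix(tp)
            if select:
                bundle = select_features(fm, self.selection_config, seed=seed)
                selected = bundle.final
            else:
                bundle, selected = None, list(fm.X.columns)
            model = TimepointModel.from_feature_matrix(
                fm, features=selected, force_include=force_include)
            try:
                res = model.fit(k=k, seed=seed, tune_evals=tune_evals)
            except ValueError as exc:
                # e.g. too few cases left at this time point to stratify
                logger.warning("%s skipped: %s", tp.name, exc)
                continue
            out.per_timepoint[tp.name] = {
                "timepoint": tp, "matrix": fm, "selection": bundle,
                "selected": selected, "results": res}
            logger.info("%s: n=%d, %d selected, median AUC %.3f",
                        tp.name, len(fm.y), len(selected), res.median("auc"))
        if run_acog:
            out.acog = self.run_acog(reps=acog_reps, seed=seed)
        return out

    def run_acog(self, reps: int = 1000, seed: int = 0) -> dict:
        """Guideline comparator on the antepartum-at-risk cohort."""
        factors = acog_factors_from_cohort(self.ehr, self.journeys, self.code_sets)
        scores = acog_risk_score(factors)
        y = self.labels.set_index("journey_id").loc[scores.total.index, "is_pe"]
        high = acog_auc_bootstrap(scores.high, y, reps=reps, seed=seed)
        total = acog_auc_bootstrap(scores.total, y, reps=reps, seed=seed)
        high.pop("aucs"), total.pop("aucs")
        return {"high_risk_only": high, "all_factors": total,
                "scores": scores, "labels": y}
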