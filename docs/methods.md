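# Methods

This note documents the modelling choices in `petimeline`: the procedures
each stage implements, the parameters that matter and their defaults, what
the synthetic cohort does and does not emulate, and the numerical and
design decisions taken where more than one reasonable option existed.

## Journey construction

Delivery events are identified from three evidence paths — delivery
diagnosis codes, vaginal/cesarean procedure codes, and labor-and-delivery
admissions — restricted to biologically female patients aged 12–50 at the
event. Evidence closer together than `dedup_window_days` (default 180; two
true deliveries cannot be that close) is merged into one event; a
procedure code dates the delivery when present, otherwise a diagnosis
code, otherwise the admission record. Pregnancy start is
`report_date − 7 × gestational_week` using gestational-week reports from
the 310 days before delivery. When reports disagree, the most recent
report wins (it is closest to delivery and least extrapolated); a
median-of-implied-starts rule is available via `JourneyConfig`. The data
window runs from `prepregnancy_days` (default 240, a determinization of
"8 months") before pregnancy start to `postpartum_days` (default 70,
i.e. 10 weeks) after delivery. Journeys whose window contains no
non-demographic events beyond the delivery evidence itself are rejected
(sparsity filter, threshold configurable); each rejection is logged with a
reason.

Because gestational weeks are reported as integers, the recovered start
date quantizes to within 0–6 days of the true start; downstream code never
assumes better than ±7-day dating.

## Digital phenotype

Case status is assigned inside the at-risk window
[gestational week 20, delivery + 70 d]:

* **Code path** — any PE diagnosis code in the window; onset = first code
  date.
* **Rule path** — a hypertension episode: two *distinct-timestamp*
  readings with SBP ≥ 140 or DBP ≥ 90 mmHg separated by ≤ 3 days (72 h,
  absolute difference), taking the earliest qualifying pair; plus
  proteinuria evidence within ±3 days of the episode's first reading —
  a proteinuria diagnosis code, a dipstick urine protein at or above
  ordinal 3 ("small" ≈ 1+), or quantitative urine protein ≥ 300 mg/24 h.
  Onset = the first high-BP day.

Decisions worth stating explicitly: the proteinuria anchor is the *first*
episode only (later episodes are not retried if the first lacks
proteinuria — the rule dates onset from the first repeating high blood
pressure); dipstick "trace" (ordinal 2) is a *predictor*, not diagnostic
evidence, so the default diagnostic threshold is ordinal ≥ 3; when both
paths fire the code path dates the onset and the label records
`source="both"`; BP pairs are searched over raw plausibility-filtered
readings, not daily aggregates. Platelet/creatinine/liver-enzyme criteria
exist in the guideline but are not part of the operational rule here.

Subtypes partition cases by onset: antepartum (before the
labor-and-delivery admission), intrapartum (admission to delivery),
postpartum (after delivery). `validate_against_icd` reports, among
code-identified cases, the fraction carrying rule evidence (an episode,
with or without anchored proteinuria) — the concordance check of the
phenotype against coding practice.

A note on monotonicity: because the proteinuria anchor is fixed to the
first episode, inserting a qualifying BP reading *earlier* than the
current anchor can in principle re-anchor the rule away from the
proteinuria evidence. The property tests therefore assert label stability
for readings added at or after the existing anchor, which is the
clinically meaningful direction.

## Time points, features, leakage

The 19 time points are the prenatal protocol: weeks
4, 8, 12, 16, 20 (monthly), 22–34 (biweekly), 35–39 (weekly), then
intrapartum and postpartum. Event cutoffs are `start + 7 × week` days for
antepartum points, delivery for intrapartum, and the window end for
postpartum. Exclusion of already-onset cases is period-consistent:
antepartum points drop cases with onset before the cutoff; the intrapartum
point drops antepartum-onset cases; the postpartum point drops ante- and
intrapartum-onset cases. The intrapartum and postpartum models therefore
*nowcast* as much as they forecast — their matrices legitimately contain
within-period treatment and vital-sign data (oxytocin, postpartum blood
pressure), and on synthetic data they reach near-perfect discrimination
because the diagnostic evidence itself is in view. The antepartum timeline
is the forecasting benchmark. PE diagnosis codes are excluded from feature
construction at every time point: they define the label.

Features per time point: demographics (age at pregnancy, race one-hots
with multi-race multi-assignment, Medicaid, tobacco/alcohol history,
parity, prior-PE and family-history flags); first-timing features (floored
gestational week of the first event in each diagnosis / medication /
procedure group, negative before pregnancy, missing if absent); per-period
(ante/intra/post) min/median/max for numeric vitals and labs, max-only for
pain scores and ordinal dipstick labs; FPCA scores (below); and
cesarean/vaginal indicators from the intrapartum point on. Vitals are
plausibility-filtered first (bounds in `VITAL_BOUNDS`, e.g. SBP 40–370
mmHg, O₂ saturation 50–100%; pain exempt). Missing values are never
imputed — the boosted trees route them natively, and the selector handles
them per its track.

The feature dictionary (column set) is determined by events up to the
cutoff across *all* journeys, while rows cover only the at-risk set; this
keeps the dictionary monotone along the timeline and independent of which
cases happen to be excluded. The leakage contract — randomizing all
post-cutoff events changes neither any matrix cell nor any model
prediction — is enforced by construction (a single `t ≤ cutoff` clip feeds
every feature family) and verified at all 19 time points in the test
suite.

## Sparse FPCA

Longitudinal vitals (DBP, SBP, O₂ saturation, pulse, respirations,
temperature, weight) and numeric labs (fibrinogen, MCH, WBC, platelets by
default; configurable) are summarized by functional principal component
scores over the antepartum domain (gestational days 0–290, 51-point
grid). The estimator is the standard sparse-design approach: a pooled
kernel-smoothed mean (Gaussian kernel; bandwidth by GCV over candidates
of 5–25% of the domain), a covariance surface smoothed from within-subject
off-diagonal cross-products (bandwidth 1.5× the mean's), measurement-error
variance σ² from the raw-minus-smoothed diagonal (floored at 10⁻⁶), and
conditional-expectation ("PACE") scores
ξ̂ᵢₖ = λₖ φₖ(tᵢ)ᵀ (Φᵢ Λ Φᵢᵀ + σ²I)⁻¹ (yᵢ − μ(tᵢ)). Scores are centered on
their training means, which removes the common offset that residual
mean-smoothing bias would otherwise inject (and makes identical curves
score exactly zero). Retained components: the smallest number reaching 99%
fraction of variance explained, capped at 10. Subjects need more than 3
observations to be scored; others get missing scores. Bases can be fitted
per training fold via `TimepointModel`; the end-to-end study object fits
one basis per time point on its training rows — at 19 time points × 10
folds × 11 signals, per-fold refitting buys nothing at the study sizes
used here.

## Selection

Two tracks reflect two missingness regimes. Sparse events (diagnoses,
medications, procedures; absence meaningfully encodable as zero) plus
demographics go to an adaptive LASSO: ridge logistic coefficients set
weights wⱼ = 1/|β̂ⱼ|, the L1 path (liblinear, C ∈ 10⁻³…10¹, 5-fold
deviance) picks the support, and an unpenalized refit supplies p-values
(penalized fallback with pseudo-inverse standard errors under separation,
flagged); keep p < 0.05. Vitals/labs (informative missingness) go to
demographics-adjusted univariate logistic fits on complete cases, ≥ 10
valid values required, keep p < 0.05. All features additionally pass
through a random forest and an XGBoost model fitted on an 80% bootstrap
with replacement; each keeps features at/above its own 75th importance
percentile, ties kept, exact zeros never kept (with sparse matrices the
75th percentile can be 0, which would otherwise select everything). The
final set intersects, per domain, the methods that scored it; an empty
intersection falls back to demographics-only with a warning. A single
bootstrap is drawn, as in the underlying procedure; repeated-bootstrap
aggregation is a possible extension.

## Models and evaluation

LightGBM classifiers (deterministic mode, single-threaded) under
`StratifiedGroupKFold` with k = 10: every journey of a patient is in
exactly one fold and class frequencies are approximately preserved.
Hyperparameter search is seeded random sampling over learning rate
(log-uniform 0.005–0.3), trees (50–500), depth (2–12), leaves (8–256),
row/column sample rates (0.5–1), L1/L2 penalties (10⁻⁸–10), and minimum
cases per leaf (5–100), scored by mean inner-fold AUC on a nested grouped
split; the default configuration (200 trees, lr 0.05, 31 leaves) is used
when tuning is disabled. Reported metrics are median and first/third
quartile across the 10 fold models. The operating threshold for
SEN/SPE/PPV/NPV is Youden's J maximized on the training folds
(fixed-specificity alternative available); PPV is always reported next to
the fold prevalence, which is the clinically meaningful comparison.

The guideline comparator sums six high-risk factors (prior PE, multifetal
gestation, chronic hypertension, diabetes, renal disease, autoimmune
disease) and six moderate-risk factors (nulliparity, BMI > 30, family
history, sociodemographic characteristics, age ≥ 35, personal-history
factors); the two composite factors count once if any member is present.
Its AUC uses the integer score directly as the ranking statistic,
bootstrapped (90% resamples with replacement, 1000 replicates, median and
quartiles; replicates with a constant score contribute AUC 0.5, the
no-information value).

## Interpretation

TreeSHAP attributions come from LightGBM's native exact computation in
log-odds; additivity φ₀ + Σφᵢ = f(x) is verified to 10⁻⁶ on every
explained sample. The relative-risk transform RRᵢ = σ(φ₀+φᵢ)/σ(φ₀) maps an
attribution to a risk ratio against the population baseline (RR = 1 at
φᵢ = 0, strictly increasing, bounded by 1/σ(φ₀)); grouped attributions sum
φ over the subset. Category contributions are the mean |φ| per category,
normalized to 100%. Moving-average curves use a centered 28-day window on
a daily grid, with gaps where no observation falls in the window.
Adjusted odds ratios are per-SD logistic coefficients adjusted for age,
race and Medicaid (configurable), with Wald 95% CIs and a flagged
penalized fallback under separation. The SHAP-rank feature sweep adds
features by mean-|φ| rank and stops when three consecutive additions each
gain < 0.002 AUC ("flatness" quantified). Networks are bipartite
(time-point squares, feature circles sized by importance; edge color
red/blue for OR >/< 1, width = importance, p-value attached), exported as
GraphML; in the per-antepartum-time-point network, features predictive at
a single time point are dropped.

## The synthetic cohort

The generator emulates the study conditions, not any real population.
Per journey: gestational length N(273, 8²) days; protocol visits at the 17
antepartum weeks with N(0, 2²)-day jitter and 85% attendance, a
pre-pregnancy baseline encounter, four intrapartum observations, and up to
three postpartum visits at 70% attendance; gestational-week reports at
half the visits and always at admission. Case prevalence 9.3% with
subtype weights 0.020/0.062/0.011 (ante/intra/postpartum) before
normalization; 30% of cases carry the diagnosis code, and 91.36% of coded
cases also carry rule evidence (uncoded cases always do — they would
otherwise be unlabelable, contradicting their planted status).

Planted signals: a +10 mmHg systolic offset ramping in linearly over the
six weeks before onset (full offset from onset; the shape is a modelling
choice, configurable); a shifted dipstick distribution throughout the
journey (cases: 65/22/8/4/1% for negative…large vs 85/12/2/0.7/0.3%);
fibrinogen rising an extra 2 mg/dL per gestational week past week 16;
MCH 1 pg lower; mild WBC/platelet/uric-acid/pulse shifts; enriched
baseline risk factors (prior PE, chronic hypertension, Medicaid, age).
Every case effect is scaled by a per-journey severity factor
(Gamma(2, ½), mean 1 — population effect sizes match the config exactly
while individual journeys vary; blood-pressure severity is attenuated to
0.5 + 0.5·Gamma so the planted mean offset is tightly identified), and
labs/pulse carry journey-level random intercepts so that repeated
measurements share a subject's own level — without them, within-journey
averaging would separate cases almost perfectly, which no real cohort
does. Rule evidence is planted as two 141–158 mmHg readings at onset and
onset + 1 day (hours apart for intrapartum onsets) plus a dipstick
"small"-or-worse within a day; journeys planted *without* rule evidence
have ambient BP capped below threshold so severe trajectories cannot
contradict the flag. A 0.2% rate of absurd vital values (SBP 400, O₂
120%) exercises the plausibility filter, and a 2% male subpopulation
exercises the cohort filters.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: coding noise and upcoding, cross-facility
fragmentation, visit cadence that depends on risk (informative
missingness), secular drift, chronic hypertensives with genuinely high
ambient BP (who would stress the rule path's specificity), correlated
multi-morbidity, and free-text anything. Effect sizes are planted, so
discrimination on synthetic data measures pipeline correctness, not
clinical attainability.

## Problem sizes

The bundled study runs on ~5000 journeys (3900 patients), 10 outer folds,
all 19 time points, with selection once per time point and default
hyperparameters; the concordance check uses a fully-coded 50%-prevalence
cohort of ~6500 journeys to accumulate ≥ 3000 coded cases. These sizes
make the full pipeline and its property checks rerunnable in minutes on a
single core while keeping every binomial tolerance meaningful; all sizes
are constructor arguments.

## Known limitations

Single-anchor proteinuria (see phenotype note); no severity grading of PE;
the ACOG comparator's composite factors are binary simplifications; FPCA
bandwidth selection is shared between mean and covariance (scaled, not
separately cross-validated); adjusted ORs are association measures, not
causal effects; and the intrapartum/postpartum models' nowcasting
character means their synthetic AUCs should not be read as forecasting
performance.
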