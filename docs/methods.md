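# Methods

## Classification model

The engine operates on two tables: a registry row per patient (diagnosis
date, stage 0–III, laterality, vital status, cause-of-death code,
prior-cancer history) and dated, coded utilization events tagged with their
source feed (inpatient procedures, ambulatory procedures, systemic therapy,
radiotherapy, cause of death). Follow-up is administratively censored at
`min(death_date, study_end)`.

Eligibility mirrors a population-based incident cohort: female, age ≥ 18,
stage 0–III, no registry histology-exclusion flag (breast lymphoma or skin
cancer of the breast, carried as a precomputed boolean because the deriving
morphology codes are configuration, not data), and survival beyond 180 days
from diagnosis. "Died within 180 days" is interpreted as
`death − diagnosis ≤ 180` days; survival to day 181 is eligible, matching
the observation window's strict start. Excluded patients are tallied under
the first matching reason in the fixed order non-female → age → stage →
histology flag → early death; any fixed order preserves the
counts-sum-to-cohort invariant, and this one follows the usual funnel
reading order. Patients with prior cancer are retained.

The observation window starts **exclusively** at `diagnosis + washout_days`
(default 180): an event dated exactly on the boundary day is washout. The
window ends inclusively at censoring; a death on the study end date still
counts for the death criterion. Each criterion is a set of code sets per
source; the procedure criterion requires the event's own (procedure) code
and its associated diagnosis code to match *on the same record*. Matching
is exact or by prefix (ICD-style hierarchies); prefix sets in which one
member is a prefix of another are rejected at load time as ambiguous.
Duplicate event rows — identical (patient, date, source, code, diagnosis
code) — count once; administrative extracts commonly duplicate rows across
feeds, and tallies are meant to count distinct events. The breast-cancer
death criterion is evaluated from the registry's death fields (and any
cause-of-death event rows), through the same code-set machinery.

One criterion met once flags the patient. Because criteria and events are
evaluated independently and aggregated as sets, the classification is
invariant under any permutation of criteria or events — a property the test
suite asserts directly. Cohort aggregation produces per-criterion patient
and event tallies, contralateral-event counts for the two
laterality-capable criteria, a mutually exclusive criterion-combination
partition over flagged patients (which must sum exactly to the flagged
count), and overall plus per-stage rates. The contralateral flag requires a
definite left/right on both the registry and a qualifying
procedure/radiotherapy event, strictly opposite; bilateral or unknown on
either side never triggers it — the flag means *probable* second primary
and a conservative rule avoids manufacturing certainty from missing
laterality. Report writers can render counts of 1–5 as "<6" (the small-cell
suppression convention of published tables); raw outputs are never
suppressed.

Ties between criteria on the same first date are kept as ties: all such
criteria are recorded and `first_event_date` is that day; no criterion
precedence exists.

## Agreement statistics

With the algorithm as index test and the (possibly adjudicated) review as
reference, the 2×2 confusion matrix yields sensitivity TP/(TP+FN),
specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN), accuracy
`p_o = (TP+TN)/n`, expected agreement
`p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/n²`, `κ = (p_o − p_e)/(1 − p_e)`
and `PABAK = 2·p_o − 1`. A statistic with a zero denominator is reported as
undefined; the others still compute. The identity `PABAK = 2·accuracy − 1`
holds to machine precision by construction and is property-tested.

Interval choices:

* **Proportions** — exact Clopper–Pearson by default (Wilson score as an
  option). The method behind published validation intervals of this kind is
  often unnamed; Clopper–Pearson reproduces the reference panel's printed
  intervals at one-decimal rounding, which is the strongest statement the
  package makes.
* **Kappa** — Fleiss–Cohen–Everitt large-sample standard error (1969
  variant without the bias term), `κ ± 1.96·SE`, truncated to [−1, 1]. This
  variant reproduces the reference panel's printed kappa interval exactly
  and agrees with `statsmodels.stats.inter_rater.cohens_kappa` to machine
  precision (used as an independent cross-check in the tests, not as the
  implementation).
* **PABAK** — the accuracy interval mapped through `2x − 1`; since PABAK is
  an affine function of accuracy, its interval is the image of the accuracy
  interval.

Adjudication (`apply_adjudication`) revises reference labels where a
case-by-case re-review of algorithm-positive/review-negative patients finds
definitive evidence in the administrative record (e.g. a pathology report);
the operation is a keyed overwrite, logged by flip direction, and an
involution when applied twice with opposite labels.

Exclusion-bias machinery: Pearson chi-squared without continuity correction
(`scipy.stats.chi2_contingency`) and the classical 1-df
Cochran–Mantel–Haenszel statistic for stage-stratified 2×2 tables
(`statsmodels` `StratifiedTable.test_null_odds`, continuity correction off —
the modern default; strata with a zero margin carry no information about
the conditional association and are skipped with a warning).

## Validation-sample design

`expected_ci_range(p, n)` answers: if the assumed value `p` were observed
among `n` effective subjects, what 95% interval would be reported?
Fractional expected success counts (`p·n`) are rounded to the nearest
integer before inversion; no standard rounding rule exists, so the choice
is documented here. For sensitivity the effective `n` is
`round(prevalence × n_per_stage)`; for specificity it is the complement.
Defaults encode the planning assumptions: per-stage SBCE prevalence
2% / 7.7% / 20% and assumed sensitivity 75/85/90%, specificity 99/95/90%
for stages I/II/III at 1000 patients per stage. Under Clopper–Pearson with
nearest-integer rounding the calculator reproduces the published planning
ranges for stage I–III specificity and stage III sensitivity exactly; the
two low-count stage-I/II sensitivity cells land within one percentage point
of the published figures (51–91 vs 52–91; 74–92 vs 75–92), consistent with
an unnamed interval method or a different rounding rule in the original
planning; the package documents rather than resolves this. This is an
expected-precision calculation, not a hypothesis-test power analysis.

Stratified sampling is uniform without replacement within stage, seeded and
deterministic; under-sized strata are taken whole with a warning.

## Synthetic cohorts

The generator emulates the joint structure of registry-linked claims, not
any real population's code frequencies. Per patient it draws stage
(defaults approximating a population stage 0–III mix: 4.8/42.7/38.2/14.3%),
diagnosis date uniform over 2009–2012 with study end 2013-12-31, laterality,
and age. A true SBCE occurs with stage-specific probability (defaults
0.04/0.02/0.077/0.20 for stages 0/I/II/III — the invasive-stage values are
the design-planning assumptions; the stage-0 value loosely echoes observed
stage-0 algorithm rates and is a simulation setting, not an estimate) at a
date uniform over post-washout follow-up.

Observable consequences of a true SBCE: with probability
`invisible_treatment_prob` (default 0.10) the patient emits **nothing** —
endocrine-only or palliative management invisible to the claims feeds;
otherwise each criterion fires independently with its detectability
(defaults 0.08 death / 0.70 procedure / 0.40 systemic / 0.45 radiotherapy).
Hence, exactly,

    P(algorithm-positive | true SBCE)
      = (1 − invisible) · (1 − Π_c (1 − detectability_c))  ≈ 0.818,

the closed form the parameter-recovery tests check the engine against.
Defaults were chosen once so this implied sensitivity and the
false-positive rate (0.06 per unaffected patient — e.g. delayed
reconstruction after the washout) sit in the range reported for validated
claims algorithms of this type. A firing death criterion sets the death
date and a matching cause code; other fired criteria emit one event
(sometimes two, `repeat_event_prob` 0.20) between the SBCE date and
censoring, on the contralateral side with probability 0.11. Every patient
also emits 1–2 primary-treatment events *inside* the washout using the same
code lists — the decoys the washout rule must ignore. Unaffected patients
may die of unrelated causes (2%, uniform over follow-up, non-matching cause
code), occasionally within 180 days, which exercises the early-death
exclusion downstream. Event dates are uniform within their admissible
windows — the least-assumption default in the absence of a timing model.

The simulated manual review flips true labels with `review_miss_prob`
(default 0.05: care received at another centre) and false labels with
`review_false_call_prob` (0.01). One global seed spawns three independent
substreams (patients, events, review), so changing event noise never
perturbs the review labels — asserted in the tests.

What the simulator does **not** model: realistic code frequencies or
per-source coding idiosyncrasies, time-to-event structure beyond uniform
dates, correlated criteria (e.g. systemic therapy conditional on procedure),
stage-dependent detectability, or review error correlated with the
administrative record. Passing recovery tests therefore demonstrates the
pipeline's internal correctness under known generating conditions, not
clinical performance on real data.

`plant_confusion_cohort` is the deterministic counterpart: given any target
(TP, FP, FN, TN) it builds TP+FP patients whose events fire the engine
(cycling through the three event-based criteria), FN+TN patients with no
post-washout qualifying events, and reference labels with exactly TP+FN
positives — so the classify→compare pipeline realizes the target exactly.
This is how the published validation panel (TP 249, FP 122, FN 43, TN 1831;
algorithm rate 16.5%, reference rate 13.0%) is reproduced end to end, and
how the 16-patient adjudication arithmetic (138 pre-revision false
positives → 122 after upgrading 16 concordant cases) is checked.

## Problem sizes and numerics

Test and acceptance runs use n = 20,000 for stochastic parameter recovery
(Monte-Carlo tolerance: 3 binomial standard errors around the closed form),
n = 3,000 for the perfect-observation check, and the 2,245-patient planted
validation cohort for the exact reproductions; these sizes give standard
errors well inside the asserted tolerances. Full population-scale results
(tens of thousands of patients with their registry-specific tallies) depend
on the real linked data and are out of scope. Interval computations use
`statsmodels`' beta-quantile Clopper–Pearson implementation; tests verify it
against an independent bisection on exact binomial tails to 1e-6, and a
10,000-replicate simulation confirms ≥ 94.5% empirical coverage at n = 292.
All date arithmetic is whole-day; codes are normalized to trimmed uppercase
at load and at match time.

## Known limitations

* Code lists ship as synthetic placeholders; nothing in this package
  validates a clinical code list.
* The engine dates an SBCE by its first qualifying event, which lags true
  onset; no local/regional/distant distinction is attempted (the criteria
  combine them by design).
* Kappa's large-sample interval can be anti-conservative for very sparse
  cells; the package truncates rather than switches to a bootstrap.
* The simulator's independence assumptions (criteria, review errors) make
  recovered operating characteristics cleaner than real validation studies
  would be.
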