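"""Synthetic linked administrative cohorts with known ground truth.

Real registry-linked utilization data cannot be shared, so this module
generates cohorts with the same joint structure the rule engine consumes:
stage-dependent second-event risk, dated coded events from multiple sources
with laterality, primary-treatment events inside the 180-day washout that
must *not* be counted, false-positive-generating events after the washout
(e.g. delayed reconstruction surgery), truly affected patients who emit no
qualifying events at all (endocrine-only or palliative management invisible
to the claims feeds), and an imperfect simulated chart review that misses
cases managed at other centres and occasionally calls a negative positive.

Generation model, per patient:

* stage, diagnosis date, laterality, age are drawn independently;
* a true SBCE occurs with a stage-specific probability; its date is uniform
  over the post-washout follow-up;
* a truly affected patient is "invisible" with probability
  ``invisible_treatment_prob`` (emits nothing); otherwise each criterion
  independently emits qualifying events with its detectability probability,
  so that P(algorithm-positive | true SBCE) =
  ``(1 - invisible) * (1 - prod_c(1 - detectability_c))`` exactly;
* unaffected patients emit a post-washout criterion-matching event with
  probability ``false_positive_event_rate``;
* every patient emits primary-treatment events inside the washout window,
  coded identically to qualifying events;
* the simulated manual review flips true labels with ``review_miss_prob``
  and false labels with ``review_false_call_prob``, independently of the
  emitted events.

A single seed feeds three independent substreams (patients, events, review)
so changing review noise never perturbs the cohort itself. All emitted codes
come from the packaged synthetic code lists.

``plant_confusion_cohort`` is the deterministic counterpart: it constructs a
cohort plus reference labels that realize any target 2x2 confusion matrix
exactly once the rule engine and label comparison are run — the end-to-end
harness for validation arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .agreement import ConfusionMatrix
from .codelists import (
    CodeListRegistry,
    Criterion,
    CodeSet,
    MatchMode,
    default_codelists,
)
from .records import (
    HealthcareEvent,
    Laterality,
    LinkedCohort,
    PatientRecord,
    Sex,
    Source,
    Stage,
    write_events,
    write_registry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "TruthTable",
    "generate_cohort",
    "simulate_manual_review",
    "plant_confusion_cohort",
    "write_cohort",
    "read_truth",
    "expected_algorithm_sensitivity",
]

_EVENT_CRITERIA = (
    Criterion.PROCEDURE_DIAGNOSIS,
    Criterion.SYSTEMIC_TREATMENT,
    Criterion.RADIOTHERAPY,
)

#: Which source a generated qualifying event uses, per criterion.
_CRITERION_SOURCE = {
    Criterion.PROCEDURE_DIAGNOSIS: Source.INPATIENT_PROCEDURE,
    Criterion.SYSTEMIC_TREATMENT: Source.SYSTEMIC_THERAPY,
    Criterion.RADIOTHERAPY: Source.RADIOTHERAPY,
}

_OPPOSITE = {Laterality.LEFT: Laterality.RIGHT, Laterality.RIGHT: Laterality.LEFT}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Stage mix defaults to the proportions of a population-based stage 0-III
    cohort; per-stage true-SBCE probabilities default to the planning
    assumptions used for validation-sample design (2% / 7.7% / 20% for
    stages I-III, 4% for stage 0). Detectability, invisibility and review
    noise defaults are chosen so the algorithm's implied sensitivity
    (~0.82) and false-positive behaviour echo published validation-scale
    performance; they are simulation settings, not clinical estimates.
    """

    n_patients: int
    seed: int = 0
    stage_distribution: Mapping[Stage, float] = field(
        default_factory=lambda: {
            Stage.S0: 0.048,
            Stage.SI: 0.427,
            Stage.SII: 0.382,
            Stage.SIII: 0.143,
        }
    )
    sbce_prob: Mapping[Stage, float] = field(
        default_factory=lambda: {
            Stage.S0: 0.04,
            Stage.SI: 0.02,
            Stage.SII: 0.077,
            Stage.SIII: 0.20,
        }
    )
    diagnosis_start: date = date(2009, 1, 1)
    diagnosis_end: date = date(2012, 12, 31)
    study_end: date = date(2013, 12, 31)
    washout_days: int = 180
    detectability: Mapping[Criterion, float] = field(
        default_factory=lambda: {
            Criterion.DEATH_BREAST_CANCER: 0.08,
            Criterion.PROCEDURE_DIAGNOSIS: 0.70,
            Criterion.SYSTEMIC_TREATMENT: 0.40,
            Criterion.RADIOTHERAPY: 0.45,
        }
    )
    invisible_treatment_prob: float = 0.10
    false_positive_event_rate: float = 0.06
    contralateral_prob: float = 0.11
    repeat_event_prob: float = 0.20
    background_death_prob: float = 0.02
    review_miss_prob: float = 0.05
    review_false_call_prob: float = 0.01

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        total = sum(self.stage_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("stage_distribution must sum to 1")
        probs = [
            *self.stage_distribution.values(),
            *self.sbce_prob.values(),
            *self.detectability.values(),
            self.invisible_treatment_prob,
            self.false_positive_event_rate,
            self.contralateral_prob,
            self.repeat_event_prob,
            self.background_death_prob,
            self.review_miss_prob,
            self.review_false_call_prob,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.diagnosis_end < self.diagnosis_start:
            raise ValueError("diagnosis window is inverted")
        washout_end = self.diagnosis_end + timedelta(days=self.washout_days)
        if self.study_end <= washout_end:
            raise ValueError(
                "study_end leaves no post-washout follow-up for late diagnoses"
            )


@dataclass(frozen=True)
class TruthRecord:
    true_sbce: bool
    true_sbce_date: Optional[date] = None
    contralateral_truth: bool = False

    def __post_init__(self) -> None:
        if self.true_sbce != (self.true_sbce_date is not None):
            raise ValueError("true_sbce_date present iff true_sbce")


TruthTable = dict[str, TruthRecord]


def expected_algorithm_sensitivity(config: SimulationConfig) -> float:
    """Closed-form P(algorithm flags SBCE | true SBCE) under the generator."""
    miss_all = 1.0
    for p in config.detectability.values():
        miss_all *= 1.0 - p
    return (1.0 - config.invisible_treatment_prob) * (1.0 - miss_all)


def _pick_code(rng: np.random.Generator, code_set: CodeSet) -> str:
    """A concrete code matching the set (expand prefixes with a digit)."""
    member = sorted(code_set.codes)[rng.integers(len(code_set.codes))]
    if code_set.match_mode is MatchMode.PREFIX:
        return member + "9"
    return member


def _uniform_date(rng: np.random.Generator, start: date, end: date) -> date:
    """Uniform calendar date in [start, end]."""
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(span + 1)))


def _qualifying_event(
    rng: np.random.Generator,
    registry: CodeListRegistry,
    pid: str,
    criterion: Criterion,
    event_date: date,
    laterality: Laterality,
) -> HealthcareEvent:
    source = _CRITERION_SOURCE[criterion]
    definition = registry[criterion]
    code_set = definition.code_sets[source.value]
    diagnosis_code = None
    if criterion is Criterion.PROCEDURE_DIAGNOSIS:
        diagnosis_code = _pick_code(
            rng, definition.diagnosis_code_sets[source.value]
        )
    return HealthcareEvent(
        patient_id=pid,
        event_date=event_date,
        source=source,
        code=_pick_code(rng, code_set),
        code_system=code_set.code_system,
        diagnosis_code=diagnosis_code,
        laterality=laterality,
    )


def _washout_events(
    rng: np.random.Generator,
    registry: CodeListRegistry,
    patient: PatientRecord,
    washout_days: int,
) -> list[HealthcareEvent]:
    """Primary-treatment events inside (diagnosis, diagnosis+washout]."""
    end = patient.diagnosis_date + timedelta(days=washout_days)
    if patient.death_date is not None:
        end = min(end, patient.death_date)
    first = patient.diagnosis_date + timedelta(days=1)
    if end < first:
        return []
    events = []
    for _ in range(1 + int(rng.integers(2))):
        criterion = _EVENT_CRITERIA[rng.integers(len(_EVENT_CRITERIA))]
        events.append(
            _qualifying_event(
                rng,
                registry,
                patient.patient_id,
                criterion,
                _uniform_date(rng, first, end),
                patient.laterality,
            )
        )
    return events


def generate_cohort(
    config: SimulationConfig,
    registry: CodeListRegistry | None = None,
) -> tuple[LinkedCohort, TruthTable]:
    """Draw a synthetic linked cohort and its ground-truth table.

    Fully deterministic for a given config (including seed). Every emitted
    code resolves against the supplied code-list registry (the packaged
    synthetic defaults unless overridden), and no qualifying event is ever
    dated inside the washout window or after censoring.
    """
    registry = registry or default_codelists()
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    rng_pat = np.random.default_rng(seeds[0])
    rng_ev = np.random.default_rng(seeds[1])

    stages = list(config.stage_distribution)
    stage_p = np.array([config.stage_distribution[s] for s in stages], dtype=float)
    stage_p = stage_p / stage_p.sum()

    patients: dict[str, PatientRecord] = {}
    events: list[HealthcareEvent] = []
    truth: TruthTable = {}
    death_cod = registry[Criterion.DEATH_BREAST_CANCER].code_sets["cause_of_death"]

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        stage = stages[int(rng_pat.choice(len(stages), p=stage_p))]
        diagnosis = _uniform_date(rng_pat, config.diagnosis_start, config.diagnosis_end)
        laterality = Laterality.LEFT if rng_pat.random() < 0.5 else Laterality.RIGHT
        age = int(rng_pat.integers(25, 91))
        prior_breast = bool(rng_pat.random() < 0.03)
        prior_other = bool(rng_pat.random() < 0.055)
        washout_end = diagnosis + timedelta(days=config.washout_days)

        is_true = rng_pat.random() < config.sbce_prob.get(stage, 0.0)
        sbce_date: Optional[date] = None
        contra = False
        death_date: Optional[date] = None
        cod_code: Optional[str] = None

        patient_events: list[HealthcareEvent] = []
        if is_true:
            sbce_date = _uniform_date(
                rng_ev, washout_end + timedelta(days=1), config.study_end
            )
            contra = bool(rng_ev.random() < config.contralateral_prob)
            invisible = rng_ev.random() < config.invisible_treatment_prob
            fired = [
                c
                for c in config.detectability
                if rng_ev.random() < config.detectability[c]
            ]
            if invisible:
                fired = []
            if Criterion.DEATH_BREAST_CANCER in fired:
                death_date = _uniform_date(rng_ev, sbce_date, config.study_end)
                cod_code = _pick_code(rng_ev, death_cod)
            event_end = death_date or config.study_end
            side = _OPPOSITE[laterality] if contra else laterality
            for criterion in fired:
                if criterion is Criterion.DEATH_BREAST_CANCER:
                    continue
                n_ev = 1 + int(rng_ev.random() < config.repeat_event_prob)
                for _ in range(n_ev):
                    patient_events.append(
                        _qualifying_event(
                            rng_ev,
                            registry,
                            pid,
                            criterion,
                            _uniform_date(rng_ev, sbce_date, event_end),
                            side,
                        )
                    )
        else:
            if rng_ev.random() < config.background_death_prob:
                death_date = _uniform_date(
                    rng_ev, diagnosis + timedelta(days=1), config.study_end
                )
                cod_code = "I259"  # non-breast cause; never matches
            censor = death_date or config.study_end
            fp_first = washout_end + timedelta(days=1)
            if rng_ev.random() < config.false_positive_event_rate and fp_first <= censor:
                # late reconstruction / unrelated systemic or radiation course
                weights = np.array([0.6, 0.15, 0.25])
                criterion = _EVENT_CRITERIA[
                    int(rng_ev.choice(len(_EVENT_CRITERIA), p=weights))
                ]
                patient_events.append(
                    _qualifying_event(
                        rng_ev,
                        registry,
                        pid,
                        criterion,
                        _uniform_date(rng_ev, fp_first, censor),
                        laterality,
                    )
                )

        patient = PatientRecord(
            patient_id=pid,
            diagnosis_date=diagnosis,
            stage=stage,
            laterality=laterality,
            sex=Sex.FEMALE,
            age_at_diagnosis=age,
            death_date=death_date,
            cause_of_death_code=cod_code,
            prior_breast_cancer=prior_breast,
            prior_other_cancer=prior_other,
        )
        patients[pid] = patient
        events.extend(
            _washout_events(rng_ev, registry, patient, config.washout_days)
        )
        events.extend(patient_events)
        truth[pid] = TruthRecord(
            true_sbce=is_true,
            true_sbce_date=sbce_date,
            contralateral_truth=contra and is_true,
        )

    cohort = LinkedCohort(
        patients=patients, events=events, study_end=config.study_end
    )
    logger.info(
        "generated %d patients, %d events, %d true SBCEs",
        len(patients),
        len(events),
        sum(t.true_sbce for t in truth.values()),
    )
    return cohort, truth


def simulate_manual_review(
    truth: TruthTable, config: SimulationConfig
) -> dict[str, bool]:
    """Imperfect chart-review labels: truth flipped with the review noise.

    Misses (a true SBCE labelled negative — care at another centre) occur
    with ``review_miss_prob``; false calls with ``review_false_call_prob``.
    Drawn from a dedicated substream of the config seed, so review labels
    are conditionally independent of the emitted events given the truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    labels: dict[str, bool] = {}
    for pid in truth:  # insertion order: deterministic
        rec = truth[pid]
        u = rng.random()
        if rec.true_sbce:
            labels[pid] = u >= config.review_miss_prob
        else:
            labels[pid] = u < config.review_false_call_prob
    return labels


def plant_confusion_cohort(
    target: ConfusionMatrix,
    seed: int,
    study_end: date = date(2013, 12, 31),
    registry: CodeListRegistry | None = None,
    washout_days: int = 180,
) -> tuple[LinkedCohort, dict[str, bool]]:
    """A cohort and reference labels realizing an exact confusion matrix.

    Constructs TP+FP patients whose events make the rule engine fire, and
    FN+TN patients with no post-washout qualifying events; the reference
    labels mark exactly TP+FN patients positive. Running the engine and
    cross-tabulating against the reference reproduces ``target`` exactly.
    The qualifying events cycle through the procedure, systemic and
    radiotherapy criteria so all event-based rules are exercised.
    """
    registry = registry or default_codelists()
    rng = np.random.default_rng(seed)
    groups = (
        ["TP"] * target.TP + ["FP"] * target.FP + ["FN"] * target.FN + ["TN"] * target.TN
    )
    rng.shuffle(groups)

    stages = [Stage.SI, Stage.SII, Stage.SIII]
    patients: dict[str, PatientRecord] = {}
    events: list[HealthcareEvent] = []
    reference: dict[str, bool] = {}
    for i, group in enumerate(groups):
        pid = f"V{i:05d}"
        diagnosis = _uniform_date(rng, date(2009, 6, 1), date(2011, 12, 31))
        laterality = Laterality.LEFT if i % 2 else Laterality.RIGHT
        patients[pid] = PatientRecord(
            patient_id=pid,
            diagnosis_date=diagnosis,
            stage=stages[i % 3],
            laterality=laterality,
        )
        if group in ("TP", "FP"):
            criterion = _EVENT_CRITERIA[i % len(_EVENT_CRITERIA)]
            first = diagnosis + timedelta(days=washout_days + 1)
            events.append(
                _qualifying_event(
                    rng,
                    registry,
                    pid,
                    criterion,
                    _uniform_date(rng, first, study_end),
                    laterality,
                )
            )
        reference[pid] = group in ("TP", "FN")
    cohort = LinkedCohort(patients=patients, events=events, study_end=study_end)
    return cohort, reference


_TRUTH_COLUMNS = ["patient_id", "true_sbce", "true_sbce_date", "contralateral_truth"]


def write_cohort(
    cohort: LinkedCohort, truth: TruthTable, directory: str | Path
) -> dict[str, Path]:
    """Write registry.csv, events.csv and truth.csv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "registry": directory / "registry.csv",
        "events": directory / "events.csv",
        "truth": directory / "truth.csv",
    }
    write_registry(cohort.patients.values(), paths["registry"])
    write_events(cohort.events, paths["events"])
    rows = [
        {
            "patient_id": pid,
            "true_sbce": int(rec.true_sbce),
            "true_sbce_date": (
                rec.true_sbce_date.isoformat() if rec.true_sbce_date else ""
            ),
            "contralateral_truth": int(rec.contralateral_truth),
        }
        for pid, rec in truth.items()
    ]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(paths["truth"], index=False)
    return paths


def read_truth(path: str | Path) -> TruthTable:
    """Read a truth.csv written by :func:`write_cohort`."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    truth: TruthTable = {}
    for _, row in frame.iterrows():
        is_true = row["true_sbce"].strip() == "1"
        truth[row["patient_id"]] = TruthRecord(
            true_sbce=is_true,
            true_sbce_date=(
                date.fromisoformat(row["true_sbce_date"]) if is_true else None
            ),
            contralateral_truth=row["contralateral_truth"].strip() == "1",
        )
    return truth
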