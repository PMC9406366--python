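"""The SBCE classification rule engine.

A patient is classified as having experienced a second breast cancer event
(SBCE) — a local/regional/distant recurrence or a new primary breast cancer —
if, strictly more than ``washout_days`` (default 180) days after the incident
diagnosis and no later than death or the study end, at least one of four
criteria is met at least once:

1. death with a breast-cancer cause-of-death code,
2. a qualifying procedure with a matching associated diagnosis on the same
   event record,
3. a qualifying systemic-therapy record,
4. a qualifying radiotherapy record.

Events inside the washout window are attributed to management of the initial
cancer and never qualify. Criteria are evaluated independently, so the
classification is invariant to the order of criteria and events. Among
patients flagged as SBCE, a probable contralateral second primary is flagged
when a qualifying procedure or radiotherapy event is on the side strictly
opposite the original cancer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .codelists import (
    LATERALITY_CAPABLE,
    CodeListRegistry,
    Criterion,
    CriterionDefinition,
)
from .records import (
    HealthcareEvent,
    Laterality,
    LinkedCohort,
    PatientRecord,
    Source,
    Stage,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmConfig",
    "SBCEClassification",
    "CohortClassification",
    "observation_window",
    "evaluate_criterion",
    "classify_patient",
    "flag_contralateral",
    "classify_cohort",
    "suppress_small_cell",
]

_OPPOSITE = {Laterality.LEFT: Laterality.RIGHT, Laterality.RIGHT: Laterality.LEFT}


@dataclass(frozen=True)
class AlgorithmConfig:
    registry: CodeListRegistry
    study_end: date
    washout_days: int = 180

    def __post_init__(self) -> None:
        if self.washout_days < 0:
            raise ValueError("washout_days must be >= 0")


@dataclass
class SBCEClassification:
    """Per-patient algorithm output."""

    patient_id: str
    is_sbce: bool
    criteria_met: frozenset[Criterion]
    qualifying_events: dict[Criterion, list[HealthcareEvent]]
    first_event_date: Optional[date]
    contralateral: bool


def observation_window(
    patient: PatientRecord, config: AlgorithmConfig
) -> tuple[date, date]:
    """The window in which events may indicate an SBCE.

    Returns ``(start, end)`` with an *exclusive* start — an event qualifies
    only if dated strictly after ``diagnosis_date + washout_days`` — and an
    inclusive end at ``min(death_date, study_end)``. ``start >= end`` means
    the window is empty.
    """
    start = patient.diagnosis_date + timedelta(days=config.washout_days)
    end = config.study_end
    if patient.death_date is not None:
        end = min(end, patient.death_date)
    return start, end


def _in_window(event_date: date, window: tuple[date, date]) -> bool:
    start, end = window
    return start < event_date <= end


def _death_event(patient: PatientRecord) -> Optional[HealthcareEvent]:
    if patient.death_date is None or not patient.cause_of_death_code:
        return None
    return HealthcareEvent(
        patient_id=patient.patient_id,
        event_date=patient.death_date,
        source=Source.CAUSE_OF_DEATH,
        code=patient.cause_of_death_code,
        code_system="",
        laterality=Laterality.UNKNOWN,
    )


def evaluate_criterion(
    patient: PatientRecord,
    events: Sequence[HealthcareEvent],
    criterion: CriterionDefinition,
    config: AlgorithmConfig,
) -> list[HealthcareEvent]:
    """Qualifying events for one criterion, deduplicated.

    The procedure+diagnosis criterion requires the event's own (procedure)
    code AND its associated diagnosis code to match on the same record. The
    breast-cancer-death criterion is evaluated against the registry's
    cause-of-death fields (and any cause_of_death-source event rows), with
    the death date subject to the same observation window. Duplicate rows —
    same patient, date, source, code and diagnosis code — count once.
    """
    window = observation_window(patient, config)
    candidates: list[HealthcareEvent] = list(events)
    if criterion.criterion_id is Criterion.DEATH_BREAST_CANCER:
        synthesized = _death_event(patient)
        if synthesized is not None:
            candidates.append(synthesized)

    qualifying: list[HealthcareEvent] = []
    seen: set[tuple] = set()
    for ev in candidates:
        if ev.patient_id != patient.patient_id:
            raise ValueError("event does not belong to patient")
        if not _in_window(ev.event_date, window):
            continue
        # Registry cause-of-death fields carry no code system; an empty
        # system on the event side means "unspecified", matched by value.
        system = ev.code_system or None
        if not criterion.matches_event(
            ev.source.value,
            ev.code,
            code_system=system,
            diagnosis_code=ev.diagnosis_code,
        ):
            continue
        if ev.dedup_key in seen:
            continue
        seen.add(ev.dedup_key)
        qualifying.append(ev)
    qualifying.sort(key=lambda ev: (ev.event_date, ev.source.value, ev.code))
    return qualifying


def flag_contralateral(
    patient: PatientRecord,
    qualifying_events: Mapping[Criterion, Sequence[HealthcareEvent]],
) -> bool:
    """Probable contralateral second primary, inferred from laterality.

    True only when the original cancer has a definite side (left/right) and
    at least one qualifying event from a laterality-capable criterion
    (procedures, radiotherapy) is on the strictly opposite side. Bilateral
    or unknown laterality on either side never raises the flag.
    """
    opposite = _OPPOSITE.get(patient.laterality)
    if opposite is None:
        return False
    for criterion, events in qualifying_events.items():
        if criterion not in LATERALITY_CAPABLE:
            continue
        if any(ev.laterality is opposite for ev in events):
            return True
    return False


def classify_patient(
    patient: PatientRecord,
    events: Sequence[HealthcareEvent],
    config: AlgorithmConfig,
) -> SBCEClassification:
    """Apply all four criteria; one criterion met once suffices."""
    qualifying: dict[Criterion, list[HealthcareEvent]] = {}
    for criterion in config.registry:
        hits = evaluate_criterion(
            patient, events, config.registry[criterion], config
        )
        if hits:
            qualifying[criterion] = hits
    criteria_met = frozenset(qualifying)
    first_date: Optional[date] = None
    if qualifying:
        first_date = min(ev.event_date for evs in qualifying.values() for ev in evs)
    return SBCEClassification(
        patient_id=patient.patient_id,
        is_sbce=bool(criteria_met),
        criteria_met=criteria_met,
        qualifying_events=qualifying,
        first_event_date=first_date,
        contralateral=flag_contralateral(patient, qualifying),
    )


@dataclass
class CohortClassification:
    """Cohort-level aggregation of per-patient classifications."""

    classifications: dict[str, SBCEClassification]
    per_criterion_patients: dict[Criterion, int]
    per_criterion_events: dict[Criterion, int]
    per_criterion_contralateral_events: dict[Criterion, int]
    combination_partition: dict[frozenset[Criterion], int]
    sbce_rate: float
    per_stage_rates: dict[Stage, float]
    n_patients: int

    @property
    def n_sbce(self) -> int:
        return sum(1 for c in self.classifications.values() if c.is_sbce)

    @property
    def n_contralateral(self) -> int:
        return sum(1 for c in self.classifications.values() if c.contralateral)

    def labels(self) -> dict[str, bool]:
        """patient_id -> algorithm SBCE flag, for agreement analysis."""
        return {pid: c.is_sbce for pid, c in self.classifications.items()}

    def to_frame(self) -> pd.DataFrame:
        """Per-patient classification table in the documented output schema."""
        rows = []
        for pid in sorted(self.classifications):
            c = self.classifications[pid]
            rows.append(
                {
                    "patient_id": pid,
                    "is_sbce": int(c.is_sbce),
                    "criteria_met": ";".join(
                        sorted(cr.value for cr in c.criteria_met)
                    ),
                    "first_event_date": (
                        c.first_event_date.isoformat() if c.first_event_date else ""
                    ),
                    "contralateral": int(c.contralateral),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "is_sbce",
                "criteria_met",
                "first_event_date",
                "contralateral",
            ],
        )

    def summary_text(self, suppress_small_cells: bool = False) -> str:
        """Cohort summary mirroring published tally-table layouts."""

        def fmt(n: int) -> str:
            return suppress_small_cell(n) if suppress_small_cells else str(n)

        lines = [
            f"Patients: {self.n_patients}",
            f"Patients with SBCEs: {fmt(self.n_sbce)} ({100 * self.sbce_rate:.1f}%)",
            f"Patients with probable contralateral second primaries: "
            f"{fmt(self.n_contralateral)}",
            "",
            "Per-criterion tallies (patients / events / contralateral events):",
        ]
        for criterion in Criterion:
            n_pat = self.per_criterion_patients.get(criterion, 0)
            n_ev = self.per_criterion_events.get(criterion, 0)
            line = f"  {criterion.value}: {fmt(n_pat)} / {fmt(n_ev)}"
            if criterion in LATERALITY_CAPABLE:
                n_contra = self.per_criterion_contralateral_events.get(criterion, 0)
                line += f" / {fmt(n_contra)}"
            lines.append(line)
        lines.append("")
        lines.append("Criterion-combination partition (mutually exclusive):")
        for combo in sorted(
            self.combination_partition,
            key=lambda s: (len(s), sorted(c.value for c in s)),
        ):
            names = "+".join(sorted(c.value for c in combo))
            lines.append(f"  {names}: {fmt(self.combination_partition[combo])}")
        lines.append("")
        lines.append("Per-stage SBCE rates:")
        for stage in Stage:
            if stage in self.per_stage_rates:
                lines.append(
                    f"  stage {stage.value}: {100 * self.per_stage_rates[stage]:.1f}%"
                )
        return "\n".join(lines)


def suppress_small_cell(n: int) -> str:
    """Render counts 1-5 as '<6', the small-cell publication convention."""
    return "<6" if 1 <= n <= 5 else str(n)


def classify_cohort(
    cohort: LinkedCohort, config: AlgorithmConfig
) -> CohortClassification:
    """Classify every patient and aggregate cohort tallies.

    Produces per-criterion patient and (deduplicated) event counts,
    contralateral-event counts for the laterality-capable criteria, the
    mutually exclusive criterion-combination partition over SBCE patients,
    and overall plus per-stage SBCE rates.
    """
    classifications: dict[str, SBCEClassification] = {}
    per_patients = {c: 0 for c in Criterion}
    per_events = {c: 0 for c in Criterion}
    per_contra = {c: 0 for c in LATERALITY_CAPABLE}
    partition: dict[frozenset[Criterion], int] = {}
    stage_totals: dict[Stage, int] = {}
    stage_sbce: dict[Stage, int] = {}

    for pid, patient in cohort.patients.items():
        result = classify_patient(patient, cohort.events_for(pid), config)
        classifications[pid] = result
        stage_totals[patient.stage] = stage_totals.get(patient.stage, 0) + 1
        if result.is_sbce:
            stage_sbce[patient.stage] = stage_sbce.get(patient.stage, 0) + 1
            partition[result.criteria_met] = partition.get(result.criteria_met, 0) + 1
        opposite = _OPPOSITE.get(patient.laterality)
        for criterion, hits in result.qualifying_events.items():
            per_patients[criterion] += 1
            per_events[criterion] += len(hits)
            if criterion in LATERALITY_CAPABLE and opposite is not None:
                per_contra[criterion] += sum(
                    1 for ev in hits if ev.laterality is opposite
                )

    n = len(cohort.patients)
    n_sbce = sum(partition.values())
    return CohortClassification(
        classifications=classifications,
        per_criterion_patients=per_patients,
        per_criterion_events=per_events,
        per_criterion_contralateral_events=per_contra,
        combination_partition=partition,
        sbce_rate=(n_sbce / n) if n else 0.0,
        per_stage_rates={
            stage: stage_sbce.get(stage, 0) / total
            for stage, total in stage_totals.items()
        },
        n_patients=n,
    )
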