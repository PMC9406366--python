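"""Cohort data model and delimited-text I/O.

The linked cohort mirrors the structure of registry-linked administrative
data: one registry row per patient (diagnosis date, stage 0–III, laterality,
vital status, cause of death, prior-cancer history) and any number of dated,
coded, source-tagged healthcare utilization events per patient. Follow-up is
administratively censored at a fixed study end date or at death, whichever
comes first.

File schemas (comma-delimited by default, tab accepted):

``registry.csv``
    patient_id, diagnosis_date, stage, laterality, sex, age_at_diagnosis,
    death_date, cause_of_death_code, prior_breast_cancer, prior_other_cancer,
    histology_exclusion_flag

``events.csv``
    patient_id, event_date, source, code_system, code, diagnosis_code,
    laterality

Dates are ISO-8601 calendar dates; booleans are written ``1``/``0``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "Laterality",
    "Sex",
    "Source",
    "PatientRecord",
    "HealthcareEvent",
    "LinkedCohort",
    "ExclusionTally",
    "CohortReadError",
    "read_cohort",
    "filter_eligible",
    "write_registry",
    "write_events",
    "EXCLUSION_ORDER",
]

#: Number of days after diagnosis within which death makes a patient
#: ineligible (and within which events are attributed to primary treatment).
EARLY_DEATH_DAYS = 180


class Stage(str, enum.Enum):
    S0 = "0"
    SI = "I"
    SII = "II"
    SIII = "III"


class Laterality(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    BILATERAL = "bilateral"
    UNKNOWN = "unknown"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Source(str, enum.Enum):
    INPATIENT_PROCEDURE = "inpatient_procedure"
    AMBULATORY_PROCEDURE = "ambulatory_procedure"
    SYSTEMIC_THERAPY = "systemic_therapy"
    RADIOTHERAPY = "radiotherapy"
    CAUSE_OF_DEATH = "cause_of_death"


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    diagnosis_date: date
    stage: Stage
    laterality: Laterality
    sex: Sex = Sex.FEMALE
    age_at_diagnosis: int = 60
    death_date: Optional[date] = None
    cause_of_death_code: Optional[str] = None
    prior_breast_cancer: bool = False
    prior_other_cancer: bool = False
    histology_exclusion: bool = False

    def __post_init__(self) -> None:
        if self.age_at_diagnosis < 0:
            raise ValueError(f"{self.patient_id}: negative age")
        if self.death_date is not None and self.death_date < self.diagnosis_date:
            raise ValueError(
                f"{self.patient_id}: death_date precedes diagnosis_date"
            )

    @property
    def follow_up_end(self) -> Optional[date]:
        return self.death_date


@dataclass(frozen=True)
class HealthcareEvent:
    patient_id: str
    event_date: date
    source: Source
    code: str
    code_system: str = ""
    diagnosis_code: Optional[str] = None
    laterality: Laterality = Laterality.UNKNOWN

    @property
    def dedup_key(self) -> tuple:
        return (
            self.patient_id,
            self.event_date,
            self.source,
            self.code,
            self.diagnosis_code,
        )


@dataclass
class LinkedCohort:
    """Validated registry + events with a common censoring date."""

    patients: dict[str, PatientRecord]
    events: list[HealthcareEvent]
    study_end: date

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.patient_id not in self.patients:
                raise ValueError(f"event for unknown patient {ev.patient_id!r}")

    def events_for(self, patient_id: str) -> list[HealthcareEvent]:
        return self._events_by_patient().get(patient_id, [])

    def _events_by_patient(self) -> dict[str, list[HealthcareEvent]]:
        cached = getattr(self, "_by_patient", None)
        if cached is None or len(cached[1]) != len(self.events):
            grouped: dict[str, list[HealthcareEvent]] = {}
            for ev in self.events:
                grouped.setdefault(ev.patient_id, []).append(ev)
            cached = (grouped, self.events)
            object.__setattr__(self, "_by_patient", cached)
        return cached[0]

    @property
    def n_patients(self) -> int:
        return len(self.patients)


class CohortReadError(ValueError):
    """Raised when input rows fail validation; carries per-row messages."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:5])
        more = f" (+{len(self.errors) - 5} more)" if len(self.errors) > 5 else ""
        super().__init__(f"{len(self.errors)} bad row(s): {preview}{more}")


_BOOL = {"1": True, "0": False, "true": True, "false": False, "": False}


def _parse_date(text: str, what: str) -> Optional[date]:
    text = text.strip()
    if not text:
        return None
    try:
        return date.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"unparseable {what} {text!r}") from exc


def _read_table(path: Path, delimiter: Optional[str]) -> pd.DataFrame:
    if delimiter is None:
        # comma default, tab accepted
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def _parse_registry_row(row: pd.Series) -> PatientRecord:
    stage_text = row.get("stage", "").strip()
    try:
        stage = Stage(stage_text)
    except ValueError:
        raise ValueError(f"unknown stage value {stage_text!r}")
    dx = _parse_date(row["diagnosis_date"], "diagnosis_date")
    if dx is None:
        raise ValueError("missing diagnosis_date")
    return PatientRecord(
        patient_id=row["patient_id"].strip(),
        diagnosis_date=dx,
        stage=stage,
        laterality=Laterality(row.get("laterality", "unknown").strip() or "unknown"),
        sex=Sex(row.get("sex", "female").strip() or "female"),
        age_at_diagnosis=int(row.get("age_at_diagnosis", "60") or 60),
        death_date=_parse_date(row.get("death_date", ""), "death_date"),
        cause_of_death_code=(row.get("cause_of_death_code", "").strip() or None),
        prior_breast_cancer=_BOOL[row.get("prior_breast_cancer", "0").strip().lower()],
        prior_other_cancer=_BOOL[row.get("prior_other_cancer", "0").strip().lower()],
        histology_exclusion=_BOOL[
            row.get("histology_exclusion_flag", "0").strip().lower()
        ],
    )


def _parse_event_row(row: pd.Series) -> HealthcareEvent:
    ev_date = _parse_date(row["event_date"], "event_date")
    if ev_date is None:
        raise ValueError("missing event_date")
    return HealthcareEvent(
        patient_id=row["patient_id"].strip(),
        event_date=ev_date,
        source=Source(row["source"].strip()),
        code=row.get("code", "").strip(),
        code_system=row.get("code_system", "").strip(),
        diagnosis_code=(row.get("diagnosis_code", "").strip() or None),
        laterality=Laterality(row.get("laterality", "unknown").strip() or "unknown"),
    )


def read_cohort(
    registry_path: str | Path,
    events_paths: str | Path | Iterable[str | Path],
    study_end: date,
    delimiter: Optional[str] = None,
    skip_bad: bool = False,
) -> LinkedCohort:
    """Read and validate a linked cohort from delimited text files.

    Orphan events (unknown patient_id) and events dated after the patient's
    censoring date ``min(death_date, study_end)`` are dropped with logged
    counts. Rows that fail to parse are collected with line numbers and
    raised as :class:`CohortReadError`, unless ``skip_bad`` is set, in which
    case they are dropped with a logged count.
    """
    if isinstance(events_paths, (str, Path)):
        events_paths = [events_paths]
    errors: list[str] = []

    patients: dict[str, PatientRecord] = {}
    reg_path = Path(registry_path)
    for idx, row in _read_table(reg_path, delimiter).iterrows():
        line = idx + 2  # header is line 1
        try:
            rec = _parse_registry_row(row)
            if rec.patient_id in patients:
                raise ValueError(f"duplicate patient_id {rec.patient_id!r}")
            patients[rec.patient_id] = rec
        except (ValueError, KeyError) as exc:
            errors.append(f"{reg_path.name}:{line}: {exc}")

    events: list[HealthcareEvent] = []
    n_orphan = 0
    n_censored = 0
    for path in events_paths:
        path = Path(path)
        for idx, row in _read_table(path, delimiter).iterrows():
            line = idx + 2
            try:
                ev = _parse_event_row(row)
            except (ValueError, KeyError) as exc:
                errors.append(f"{path.name}:{line}: {exc}")
                continue
            patient = patients.get(ev.patient_id)
            if patient is None:
                n_orphan += 1
                continue
            censor = study_end
            if patient.death_date is not None:
                censor = min(censor, patient.death_date)
            if ev.event_date > censor:
                n_censored += 1
                continue
            events.append(ev)

    if errors and not skip_bad:
        raise CohortReadError(errors)
    if errors:
        logger.warning("skipped %d unparseable row(s)", len(errors))
    if n_orphan:
        logger.info("dropped %d orphan event(s) with unknown patient_id", n_orphan)
    if n_censored:
        logger.info("dropped %d event(s) dated after censoring", n_censored)
    return LinkedCohort(patients=patients, events=events, study_end=study_end)


#: Fixed precedence of exclusion reasons; each excluded patient is counted
#: once, under the first reason that applies.
EXCLUSION_ORDER = (
    "non_female",
    "under_18",
    "stage_out_of_range",
    "histology_exclusion",
    "early_death",
)


@dataclass
class ExclusionTally:
    counts: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    @property
    def excluded(self) -> int:
        return sum(self.counts.values())


def _exclusion_reason(patient: PatientRecord) -> Optional[str]:
    if patient.sex is not Sex.FEMALE:
        return "non_female"
    if patient.age_at_diagnosis < 18:
        return "under_18"
    if patient.stage not in Stage:
        return "stage_out_of_range"  # unreachable with validated input
    if patient.histology_exclusion:
        return "histology_exclusion"
    if (
        patient.death_date is not None
        and (patient.death_date - patient.diagnosis_date).days <= EARLY_DEATH_DAYS
    ):
        return "early_death"
    return None


def filter_eligible(cohort: LinkedCohort) -> tuple[LinkedCohort, ExclusionTally]:
    """Apply the cohort eligibility rules and tally exclusions by reason.

    Eligible patients are female, aged 18+, stage 0–III, not carrying the
    registry histology-exclusion flag (breast lymphoma / skin cancer of the
    breast), and not dead within 180 days of diagnosis. Death on day 181 or
    later is eligible. Prior cancer history does not exclude.
    """
    tally = ExclusionTally(counts={reason: 0 for reason in EXCLUSION_ORDER})
    kept: dict[str, PatientRecord] = {}
    for pid, patient in cohort.patients.items():
        reason = _exclusion_reason(patient)
        if reason is None:
            kept[pid] = patient
        else:
            tally.counts[reason] += 1
    tally.retained = len(kept)
    events = [ev for ev in cohort.events if ev.patient_id in kept]
    return (
        LinkedCohort(patients=kept, events=events, study_end=cohort.study_end),
        tally,
    )


_REGISTRY_COLUMNS = [
    "patient_id",
    "diagnosis_date",
    "stage",
    "laterality",
    "sex",
    "age_at_diagnosis",
    "death_date",
    "cause_of_death_code",
    "prior_breast_cancer",
    "prior_other_cancer",
    "histology_exclusion_flag",
]

_EVENT_COLUMNS = [
    "patient_id",
    "event_date",
    "source",
    "code_system",
    "code",
    "diagnosis_code",
    "laterality",
]


def write_registry(patients: Iterable[PatientRecord], path: str | Path) -> None:
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "diagnosis_date": p.diagnosis_date.isoformat(),
                "stage": p.stage.value,
                "laterality": p.laterality.value,
                "sex": p.sex.value,
                "age_at_diagnosis": p.age_at_diagnosis,
                "death_date": p.death_date.isoformat() if p.death_date else "",
                "cause_of_death_code": p.cause_of_death_code or "",
                "prior_breast_cancer": int(p.prior_breast_cancer),
                "prior_other_cancer": int(p.prior_other_cancer),
                "histology_exclusion_flag": int(p.histology_exclusion),
            }
        )
    pd.DataFrame(rows, columns=_REGISTRY_COLUMNS).to_csv(path, index=False)


def write_events(events: Iterable[HealthcareEvent], path: str | Path) -> None:
    rows = []
    for ev in events:
        rows.append(
            {
                "patient_id": ev.patient_id,
                "event_date": ev.event_date.isoformat(),
                "source": ev.source.value,
                "code_system": ev.code_system,
                "code": ev.code,
                "diagnosis_code": ev.diagnosis_code or "",
                "laterality": ev.laterality.value,
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)
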