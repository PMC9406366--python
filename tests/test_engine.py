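import csv
import random
from datetime import date, timedelta

import pytest

from sbce.codelists import Criterion
from sbce.engine import (
    AlgorithmConfig,
    classify_cohort,
    classify_patient,
    evaluate_criterion,
    flag_contralateral,
    observation_window,
    suppress_small_cell,
)
from sbce.records import (
    HealthcareEvent,
    Laterality,
    LinkedCohort,
    PatientRecord,
    Source,
    Stage,
    filter_eligible,
)
from sbce.simulate import SimulationConfig, generate_cohort

from conftest import DATA, STUDY_END


def patient(pid="P1", dx=date(2010, 1, 1), laterality=Laterality.LEFT, **kw):
    return PatientRecord(
        patient_id=pid, diagnosis_date=dx, stage=Stage.SII, laterality=laterality, **kw
    )


def rt_event(pid="P1", day=200, dx=date(2010, 1, 1), code="RT100",
             laterality=Laterality.UNKNOWN):
    return HealthcareEvent(
        patient_id=pid,
        event_date=dx + timedelta(days=day),
        source=Source.RADIOTHERAPY,
        code=code,
        code_system="RT-SYN",
        laterality=laterality,
    )


class TestObservationWindow:
    def test_window_spans_washout_end_to_study_end(self, config):
        start, end = observation_window(patient(dx=date(2010, 1, 1)), config)
        assert start == date(2010, 6, 30)  # diagnosis + 180 days, exclusive
        assert end == date(2013, 12, 31)

    def test_death_truncates_window(self, config):
        p = patient(dx=date(2012, 1, 1), death_date=date(2012, 5, 1),
                    cause_of_death_code="C509")
        start, end = observation_window(p, config)
        assert start > end  # empty window

    def test_event_on_washout_boundary_day_is_excluded(self, config):
        p = patient(dx=date(2010, 1, 1))
        on_boundary = rt_event(day=180)
        past_boundary = rt_event(day=181)
        rt = config.registry[Criterion.RADIOTHERAPY]
        assert evaluate_criterion(p, [on_boundary], rt, config) == []
        assert evaluate_criterion(p, [past_boundary], rt, config) == [past_boundary]


class TestEvaluateCriterion:
    def test_matching_radiotherapy_event_qualifies(self, config):
        hits = evaluate_criterion(
            patient(), [rt_event()], config.registry[Criterion.RADIOTHERAPY], config
        )
        assert len(hits) == 1

    def test_procedure_requires_both_codes_on_same_event(self, config):
        proc = config.registry[Criterion.PROCEDURE_DIAGNOSIS]
        base = dict(
            patient_id="P1",
            event_date=date(2011, 1, 1),
            source=Source.INPATIENT_PROCEDURE,
            code="1YM89",
            code_system="CCI-SYN",
        )
        good = HealthcareEvent(**base, diagnosis_code="C509")
        bad_dx = HealthcareEvent(**base, diagnosis_code="Z000")
        no_dx = HealthcareEvent(**base)
        assert evaluate_criterion(patient(), [good], proc, config) == [good]
        assert evaluate_criterion(patient(), [bad_dx], proc, config) == []
        assert evaluate_criterion(patient(), [no_dx], proc, config) == []

    def test_two_distinct_events_count_twice_for_one_patient(self, config):
        events = [rt_event(day=200), rt_event(day=300)]
        hits = evaluate_criterion(
            patient(), events, config.registry[Criterion.RADIOTHERAPY], config
        )
        assert len(hits) == 2

    def test_duplicate_rows_count_once(self, config):
        events = [rt_event(day=200), rt_event(day=200)]
        hits = evaluate_criterion(
            patient(), events, config.registry[Criterion.RADIOTHERAPY], config
        )
        assert len(hits) == 1

    def test_death_criterion_from_registry_fields(self, config):
        dead = patient(dx=date(2010, 1, 1), death_date=date(2012, 1, 1),
                       cause_of_death_code="C509")
        other_cause = patient(dx=date(2010, 1, 1), death_date=date(2012, 1, 1),
                              cause_of_death_code="I259")
        death = config.registry[Criterion.DEATH_BREAST_CANCER]
        assert len(evaluate_criterion(dead, [], death, config)) == 1
        assert evaluate_criterion(other_cause, [], death, config) == []


class TestClassifyPatient:
    def test_one_criterion_once_suffices(self, config):
        sys_event = HealthcareEvent(
            patient_id="P1",
            event_date=date(2011, 1, 1),
            source=Source.SYSTEMIC_THERAPY,
            code="SYS001",
            code_system="DIN-SYN",
        )
        result = classify_patient(patient(), [sys_event], config)
        assert result.is_sbce
        assert result.criteria_met == {Criterion.SYSTEMIC_TREATMENT}
        assert result.first_event_date == date(2011, 1, 1)

    def test_washout_only_events_do_not_classify(self, config):
        result = classify_patient(patient(), [rt_event(day=100)], config)
        assert not result.is_sbce
        assert result.criteria_met == frozenset()
        assert result.first_event_date is None

    def test_order_of_events_and_criteria_is_irrelevant(self, config, registry):
        events = [
            rt_event(day=250),
            HealthcareEvent(
                patient_id="P1",
                event_date=date(2010, 9, 1),
                source=Source.SYSTEMIC_THERAPY,
                code="SYS002",
                code_system="DIN-SYN",
            ),
        ]
        baseline = classify_patient(patient(), events, config)
        rng = random.Random(0)
        for _ in range(5):
            shuffled = events[:]
            rng.shuffle(shuffled)
            again = classify_patient(patient(), shuffled, config)
            assert again.criteria_met == baseline.criteria_met
            assert again.first_event_date == baseline.first_event_date
            assert again.is_sbce == baseline.is_sbce


class TestContralateral:
    def test_opposite_sided_event_flags(self, config):
        p = patient(laterality=Laterality.LEFT)
        hits = {Criterion.RADIOTHERAPY: [rt_event(laterality=Laterality.RIGHT)]}
        assert flag_contralateral(p, hits)

    @pytest.mark.parametrize(
        ("patient_side", "event_side"),
        [
            (Laterality.LEFT, Laterality.UNKNOWN),
            (Laterality.LEFT, Laterality.LEFT),
            (Laterality.LEFT, Laterality.BILATERAL),
            (Laterality.BILATERAL, Laterality.LEFT),
            (Laterality.UNKNOWN, Laterality.RIGHT),
        ],
    )
    def test_non_opposite_or_missing_never_flags(self, config, patient_side, event_side):
        p = patient(laterality=patient_side)
        hits = {Criterion.RADIOTHERAPY: [rt_event(laterality=event_side)]}
        assert not flag_contralateral(p, hits)

    def test_non_lateral_criterion_never_flags(self, config):
        p = patient(laterality=Laterality.LEFT)
        sys_event = HealthcareEvent(
            patient_id="P1",
            event_date=date(2011, 1, 1),
            source=Source.SYSTEMIC_THERAPY,
            code="SYS001",
            laterality=Laterality.RIGHT,
        )
        assert not flag_contralateral(p, {Criterion.SYSTEMIC_TREATMENT: [sys_event]})


class TestClassifyCohort:
    def test_zero_events_means_zero_everything(self, config):
        cohort = LinkedCohort(
            patients={"A": patient("A")}, events=[], study_end=STUDY_END
        )
        result = classify_cohort(cohort, config)
        assert result.sbce_rate == 0.0
        assert sum(result.per_criterion_patients.values()) == 0
        assert result.combination_partition == {}

    def test_fixture_tallies_match_manifest(self, config, fixture_cohort,
                                            fixture_manifest):
        eligible, _ = filter_eligible(fixture_cohort)
        result = classify_cohort(eligible, config)
        m = fixture_manifest
        assert result.n_sbce == m["sbce_patients"]
        assert result.n_contralateral == m["contralateral_patients"]
        assert {
            c.value: n for c, n in result.per_criterion_patients.items()
        } == m["per_criterion_patients"]
        assert {
            c.value: n for c, n in result.per_criterion_events.items()
        } == m["per_criterion_events"]
        assert {
            c.value: n for c, n in result.per_criterion_contralateral_events.items()
        } == m["per_criterion_contralateral_events"]
        partition = {
            "+".join(sorted(c.value for c in combo)): n
            for combo, n in result.combination_partition.items()
        }
        expected = {
            "+".join(sorted(k.split("+"))): v
            for k, v in m["combination_partition"].items()
        }
        assert partition == expected
        sbce_ids = {pid for pid, c in result.classifications.items() if c.is_sbce}
        assert sbce_ids == set(m["sbce_patient_ids"])
        contra_ids = {
            pid for pid, c in result.classifications.items() if c.contralateral
        }
        assert contra_ids == set(m["contralateral_patient_ids"])

    def test_fixture_contralateral_matches_independent_scan(self, config,
                                                            fixture_cohort):
        """Brute-force laterality scan over the raw event file."""
        eligible, _ = filter_eligible(fixture_cohort)
        result = classify_cohort(eligible, config)
        opposite = {"left": "right", "right": "left"}
        expected = set()
        for pid, cls in result.classifications.items():
            side = eligible.patients[pid].laterality.value
            if side not in opposite:
                continue
            with open(DATA / "fixture_events.csv") as fh:
                for row in csv.DictReader(fh):
                    if (
                        row["patient_id"] == pid
                        and row["source"] in ("inpatient_procedure",
                                              "ambulatory_procedure",
                                              "radiotherapy")
                        and row["laterality"] == opposite[side]
                    ):
                        in_hits = any(
                            ev.event_date.isoformat() == row["event_date"]
                            and ev.code == row["code"]
                            for hits in cls.qualifying_events.values()
                            for ev in hits
                        )
                        if in_hits:
                            expected.add(pid)
        assert {
            pid for pid, c in result.classifications.items() if c.contralateral
        } == expected

    def test_partition_sums_to_sbce_count_and_rate(self, config, fixture_cohort):
        eligible, _ = filter_eligible(fixture_cohort)
        result = classify_cohort(eligible, config)
        assert sum(result.combination_partition.values()) == result.n_sbce
        assert result.sbce_rate == result.n_sbce / eligible.n_patients
        for criterion, n_pat in result.per_criterion_patients.items():
            if n_pat >= 1:
                assert result.per_criterion_events[criterion] >= n_pat


@pytest.fixture(scope="module")
def simulated(config):
    sim = SimulationConfig(n_patients=600, seed=11)
    cohort, _ = generate_cohort(sim)
    eligible, _ = filter_eligible(cohort)
    return eligible, classify_cohort(eligible, config)


class TestInvariantsOnSimulatedCohorts:

    def test_washout_safety(self, simulated, config):
        cohort, result = simulated
        for pid, cls in result.classifications.items():
            dx = cohort.patients[pid].diagnosis_date
            for hits in cls.qualifying_events.values():
                for ev in hits:
                    assert (ev.event_date - dx).days > config.washout_days

    def test_no_qualifying_event_after_censoring(self, simulated, config):
        cohort, result = simulated
        for pid, cls in result.classifications.items():
            p = cohort.patients[pid]
            end = min(config.study_end, p.death_date or config.study_end)
            for hits in cls.qualifying_events.values():
                for ev in hits:
                    assert ev.event_date <= end

    def test_adding_event_never_unflags(self, simulated, config):
        cohort, result = simulated
        extra_by_pid = {}
        for pid in list(cohort.patients)[:50]:
            extra_by_pid[pid] = rt_event(
                pid=pid, dx=cohort.patients[pid].diagnosis_date, day=181
            )
        for pid, extra in extra_by_pid.items():
            p = cohort.patients[pid]
            if extra.event_date > min(config.study_end,
                                      p.death_date or config.study_end):
                continue
            before = result.classifications[pid]
            after = classify_patient(p, cohort.events_for(pid) + [extra], config)
            assert after.is_sbce >= before.is_sbce

    def test_removing_all_events_forces_negative(self, simulated, config):
        cohort, _ = simulated
        for pid in list(cohort.patients)[:20]:
            p = cohort.patients[pid]
            if p.cause_of_death_code:
                continue  # death criterion needs no events
            assert not classify_patient(p, [], config).is_sbce


def test_small_cell_suppression_convention():
    assert suppress_small_cell(0) == "0"
    assert [suppress_small_cell(n) for n in range(1, 6)] == ["<6"] * 5
    assert suppress_small_cell(6) == "6"


def test_summary_text_renders_tallies_and_suppression(config, fixture_cohort):
    eligible, _ = filter_eligible(fixture_cohort)
    result = classify_cohort(eligible, config)
    plain = result.summary_text()
    for criterion in Criterion:
        assert criterion.value in plain
    suppressed = result.summary_text(suppress_small_cells=True)
    assert "<6" in suppressed  # death criterion tallies 1 patient here
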