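import json
from datetime import date
from pathlib import Path

import pytest

from sbce import (
    AlgorithmConfig,
    SimulationConfig,
    Stage,
    default_codelists,
    generate_cohort,
    read_cohort,
)

DATA = Path(__file__).parent / "data"
STUDY_END = date(2013, 12, 31)


@pytest.fixture(scope="session")
def registry():
    return default_codelists()


@pytest.fixture(scope="session")
def config(registry):
    return AlgorithmConfig(registry=registry, study_end=STUDY_END)


@pytest.fixture(scope="session")
def fixture_manifest():
    with open(DATA / "fixture_manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def fixture_cohort():
    return read_cohort(
        DATA / "fixture_registry.csv", DATA / "fixture_events.csv", STUDY_END
    )


@pytest.fixture(scope="session")
def default_sim_config():
    """Default noisy simulation over invasive stages, validation-design rates."""
    return SimulationConfig(
        n_patients=20_000,
        seed=20130101,
        stage_distribution={Stage.SI: 1 / 3, Stage.SII: 1 / 3, Stage.SIII: 1 / 3},
    )


@pytest.fixture(scope="session")
def default_sim(default_sim_config):
    """One shared large simulated cohort (generation is the slow part)."""
    cohort, truth = generate_cohort(default_sim_config)
    return cohort, truth
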