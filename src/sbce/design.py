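"""Validation-sample design: stratified sampling and expected CI ranges.

Validating a claims algorithm against chart review requires enough truly
positive patients in the review sample. Because early-stage breast cancer is
common but rarely recurs, a natural (proportional) sample would contain few
stage-III patients and few events; the design therefore samples the three
invasive stages at *equal* allocation (default 1000 per stage) and computes,
a priori, the range of sensitivity/specificity estimates one could expect to
observe given assumed per-stage recurrence prevalences and assumed test
performance.

The "expected range" for, say, sensitivity at stage II is the 95% confidence
interval around the assumed sensitivity when it is observed among the
expected number of truly positive patients in that stratum
(``round(prevalence * n_per_stage)``). This reproduces an expected-precision
calculation, not a formal power analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import proportion_ci
from .records import LinkedCohort, Stage

logger = logging.getLogger(__name__)

__all__ = [
    "DesignAssumptions",
    "stratified_sample",
    "expected_ci_range",
    "design_table",
]


@dataclass(frozen=True)
class DesignAssumptions:
    """Per-stage planning assumptions for the validation sample.

    Defaults: SBCE prevalence 2% / 7.7% / 20%, assumed sensitivity
    75% / 85% / 90% and specificity 99% / 95% / 90% for stages I/II/III,
    with 1000 patients sampled per stage.
    """

    prevalence: dict[Stage, float] = field(
        default_factory=lambda: {Stage.SI: 0.02, Stage.SII: 0.077, Stage.SIII: 0.20}
    )
    sensitivity: dict[Stage, float] = field(
        default_factory=lambda: {Stage.SI: 0.75, Stage.SII: 0.85, Stage.SIII: 0.90}
    )
    specificity: dict[Stage, float] = field(
        default_factory=lambda: {Stage.SI: 0.99, Stage.SII: 0.95, Stage.SIII: 0.90}
    )
    n_per_stage: int = 1000

    def __post_init__(self) -> None:
        if self.n_per_stage < 1:
            raise ValueError("n_per_stage must be >= 1")
        for mapping in (self.prevalence, self.sensitivity, self.specificity):
            for stage, p in mapping.items():
                if not 0.0 < p <= 1.0:
                    raise ValueError(f"proportion out of range for stage {stage}")


def stratified_sample(
    cohort: LinkedCohort,
    n_per_stage: int,
    strata: list[Stage],
    seed: int,
) -> list[str]:
    """Equal-allocation random sample of patient ids within each stage.

    Uniform sampling without replacement within each stratum, deterministic
    for a given seed. If a stratum holds fewer than ``n_per_stage`` eligible
    patients, the whole stratum is taken with a warning; an empty stratum
    contributes nothing.
    """
    rng = np.random.default_rng(seed)
    by_stage: dict[Stage, list[str]] = {stage: [] for stage in strata}
    for pid in sorted(cohort.patients):
        stage = cohort.patients[pid].stage
        if stage in by_stage:
            by_stage[stage].append(pid)
    sampled: list[str] = []
    for stage in strata:
        pool = by_stage[stage]
        if not pool:
            logger.warning("stratum %s is empty; sampled 0", stage.value)
            continue
        if len(pool) <= n_per_stage:
            if len(pool) < n_per_stage:
                logger.warning(
                    "stratum %s has %d < %d patients; taking all",
                    stage.value,
                    len(pool),
                    n_per_stage,
                )
            sampled.extend(pool)
            continue
        picks = rng.choice(len(pool), size=n_per_stage, replace=False)
        sampled.extend(pool[i] for i in sorted(picks))
    return sampled


def expected_ci_range(
    assumed_value: float,
    effective_n: int,
    method: str = "clopper_pearson",
) -> tuple[int, int]:
    """Expected observable 95% CI, as integer percentages.

    The assumed proportion is converted to a success count by nearest-integer
    rounding before interval inversion (the convention adopted here; no
    standard rule exists for fractional expected counts).
    """
    if effective_n < 1:
        raise ValueError("effective_n must be >= 1 (zero is undefined)")
    if not 0.0 <= assumed_value <= 1.0:
        raise ValueError("assumed_value must be in [0, 1]")
    x = int(round(assumed_value * effective_n))
    lower, upper = proportion_ci(x, effective_n, method=method)
    return round(100.0 * lower), round(100.0 * upper)


def design_table(
    assumptions: DesignAssumptions | None = None,
    method: str = "clopper_pearson",
) -> pd.DataFrame:
    """Per-stage table of effective sizes and expected sens/spec ranges."""
    a = assumptions or DesignAssumptions()
    rows = []
    for stage in a.prevalence:
        n_pos = int(round(a.prevalence[stage] * a.n_per_stage))
        n_neg = a.n_per_stage - n_pos
        sens_range = expected_ci_range(a.sensitivity[stage], n_pos, method)
        spec_range = expected_ci_range(a.specificity[stage], n_neg, method)
        rows.append(
            {
                "stage": stage.value,
                "prevalence": a.prevalence[stage],
                "n_per_stage": a.n_per_stage,
                "n_sensitivity": n_pos,
                "n_specificity": n_neg,
                "assumed_sensitivity": a.sensitivity[stage],
                "expected_sensitivity_range": f"{sens_range[0]}-{sens_range[1]}%",
                "assumed_specificity": a.specificity[stage],
                "expected_specificity_range": f"{spec_range[0]}-{spec_range[1]}%",
            }
        )
    return pd.DataFrame(rows)
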