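"""Diagnostic agreement between the algorithm and a reference standard.

Validation compares algorithm SBCE labels (the index test) with a manual
record review (the reference standard) in a 2x2 confusion matrix and derives
sensitivity, specificity, predictive values, accuracy, Cohen's kappa and the
prevalence-adjusted bias-adjusted kappa

    PABAK = 2 * p_o - 1,

where p_o is the observed agreement. Kappa corrects agreement for chance via
the marginal expected agreement p_e, but is depressed when prevalence is far
from 50%; PABAK removes that dependence and is reported alongside.

Confidence intervals: exact Clopper-Pearson (default) or Wilson score
intervals for the binomial proportions; the Fleiss-Cohen-Everitt large-sample
standard error for kappa (Fleiss, Cohen & Everitt 1969, Psychol. Bull. 72,
323-327); and the PABAK interval obtained from the accuracy interval through
the affine map 2x - 1, consistent with PABAK's definition.

The module also provides the reference-label adjudication override (revising
manual-review labels when administrative data hold definitive evidence) and
the stratified exclusion-bias tests: Pearson chi-squared and the
Cochran-Mantel-Haenszel chi-square for 2x2 tables stratified by stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "AgreementReport",
    "build_confusion",
    "agreement_stats",
    "proportion_ci",
    "apply_adjudication",
    "chi_squared_independence",
    "cmh_test",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 patient counts, algorithm as index test, review as truth."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def as_array(self) -> np.ndarray:
        """Rows: algorithm +/-; columns: reference +/-."""
        return np.array([[self.TP, self.FP], [self.FN, self.TN]], dtype=float)


def build_confusion(
    algorithm_labels: Mapping[str, bool],
    reference_labels: Mapping[str, bool],
) -> ConfusionMatrix:
    """Cross-tabulate two boolean label maps over identical patient sets."""
    alg_keys, ref_keys = set(algorithm_labels), set(reference_labels)
    if alg_keys != ref_keys:
        diff = sorted(alg_keys ^ ref_keys)
        preview = ", ".join(diff[:10]) + (" ..." if len(diff) > 10 else "")
        raise ValueError(
            f"label key sets differ on {len(diff)} patient(s): {preview}"
        )
    tp = fp = fn = tn = 0
    for pid, alg in algorithm_labels.items():
        ref = reference_labels[pid]
        if alg and ref:
            tp += 1
        elif alg:
            fp += 1
        elif ref:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(TP=tp, FP=fp, FN=fn, TN=tn)


def proportion_ci(
    x: int, n: int, method: str = "clopper_pearson"
) -> tuple[float, float]:
    """Two-sided 95% confidence interval for a binomial proportion."""
    if not 0 <= x <= n or n < 1:
        raise ValueError("require 0 <= x <= n and n >= 1")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}[method]
    lower, upper = proportion_confint(x, n, alpha=0.05, method=sm_method)
    return float(lower), float(upper)


def _kappa_fleiss_se(cm: ConfusionMatrix, kappa: float, p_e: float) -> float:
    """Fleiss-Cohen-Everitt large-sample SE of Cohen's kappa (2x2)."""
    n = cm.n
    p = cm.as_array() / n  # p[i, j]: algorithm i, reference j
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    one_minus_k = 1.0 - kappa
    a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * one_minus_k) ** 2 for i in range(2)
    )
    b = one_minus_k**2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    c = (kappa - p_e * one_minus_k) ** 2
    var = (a + b - c) / (n * (1.0 - p_e) ** 2)
    return math.sqrt(max(var, 0.0))


@dataclass
class AgreementReport:
    """Point estimates and 95% CIs for the agreement statistics.

    Point estimates are stored at full precision on the proportion scale
    (kappa and PABAK on [-1, 1]); :meth:`format_table` renders percentages
    to one decimal. A statistic whose denominator is zero is ``None``.
    """

    n: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    observed_agreement: Optional[float]
    expected_agreement: Optional[float]
    kappa: Optional[float]
    pabak: Optional[float]
    ci_95: dict[str, tuple[float, float]] = field(default_factory=dict)

    _ORDER = (
        "sensitivity",
        "specificity",
        "ppv",
        "npv",
        "accuracy",
        "kappa",
        "pabak",
    )

    def as_percentages(self) -> dict[str, Optional[float]]:
        """Point estimates as percentages rounded to one decimal."""
        out: dict[str, Optional[float]] = {}
        for name in self._ORDER:
            value = getattr(self, name)
            out[name] = None if value is None else round(100.0 * value, 1)
        return out

    def format_table(self) -> str:
        """Text report with '% (95% CI)' cells, one decimal."""
        header = f"N = {self.n}"
        lines = [header]
        for name in self._ORDER:
            value = getattr(self, name)
            if value is None:
                lines.append(f"{name:>12}: undefined")
                continue
            cell = f"{100 * value:.1f}"
            if name in self.ci_95:
                lo, hi = self.ci_95[name]
                cell += f" ({100 * lo:.1f}-{100 * hi:.1f})"
            lines.append(f"{name:>12}: {cell}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "estimates_pct": self.as_percentages(),
            "ci_95_pct": {
                k: [round(100 * lo, 1), round(100 * hi, 1)]
                for k, (lo, hi) in self.ci_95.items()
            },
        }


def agreement_stats(
    cm: ConfusionMatrix,
    ci_method: str = "clopper_pearson",
    kappa_ci_method: str = "fleiss",
) -> AgreementReport:
    """All agreement statistics with 95% confidence intervals.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); PPV = TP/(TP+FP);
    NPV = TN/(TN+FN); accuracy = p_o = (TP+TN)/n;
    p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / n^2;
    kappa = (p_o - p_e)/(1 - p_e); PABAK = 2 p_o - 1.
    """
    if cm.n == 0:
        raise ValueError("confusion matrix is empty")
    if kappa_ci_method != "fleiss":
        raise ValueError(f"unknown kappa CI method {kappa_ci_method!r}")
    n = cm.n

    def ratio(x: int, d: int) -> Optional[float]:
        return x / d if d > 0 else None

    sens = ratio(cm.TP, cm.TP + cm.FN)
    spec = ratio(cm.TN, cm.TN + cm.FP)
    ppv = ratio(cm.TP, cm.TP + cm.FP)
    npv = ratio(cm.TN, cm.TN + cm.FN)
    p_o = (cm.TP + cm.TN) / n
    p_e = ((cm.TP + cm.FP) * (cm.TP + cm.FN) + (cm.FN + cm.TN) * (cm.FP + cm.TN)) / (
        n * n
    )
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else None
    pabak = 2.0 * p_o - 1.0

    ci: dict[str, tuple[float, float]] = {}
    for name, x, d in (
        ("sensitivity", cm.TP, cm.TP + cm.FN),
        ("specificity", cm.TN, cm.TN + cm.FP),
        ("ppv", cm.TP, cm.TP + cm.FP),
        ("npv", cm.TN, cm.TN + cm.FN),
        ("accuracy", cm.TP + cm.TN, n),
    ):
        if d > 0:
            ci[name] = proportion_ci(x, d, method=ci_method)
    if kappa is not None:
        se = _kappa_fleiss_se(cm, kappa, p_e)
        ci["kappa"] = (
            max(kappa - _Z95 * se, -1.0),
            min(kappa + _Z95 * se, 1.0),
        )
    acc_lo, acc_hi = ci["accuracy"]
    ci["pabak"] = (2.0 * acc_lo - 1.0, 2.0 * acc_hi - 1.0)

    return AgreementReport(
        n=n,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=p_o,
        observed_agreement=p_o,
        expected_agreement=p_e,
        kappa=kappa,
        pabak=pabak,
        ci_95=ci,
    )


def apply_adjudication(
    reference_labels: Mapping[str, bool],
    overrides: Mapping[str, bool],
) -> dict[str, bool]:
    """Revise reference labels where adjudication found definitive evidence.

    Every override key must already exist in the reference; flips are logged
    by direction. Returns a new label map.
    """
    unknown = sorted(set(overrides) - set(reference_labels))
    if unknown:
        raise ValueError(
            f"override for unknown patient(s): {', '.join(unknown[:10])}"
        )
    revised = dict(reference_labels)
    to_positive = to_negative = 0
    for pid, label in overrides.items():
        if revised[pid] != label:
            if label:
                to_positive += 1
            else:
                to_negative += 1
        revised[pid] = bool(label)
    logger.info(
        "adjudication flipped %d label(s) to positive, %d to negative",
        to_positive,
        to_negative,
    )
    return revised


def chi_squared_independence(
    table: Sequence[Sequence[int]] | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all row and column sums must be positive")
    stat, p, dof, _ = chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


def _is_degenerate(table: np.ndarray) -> bool:
    return (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()


def cmh_test(
    strata: Sequence[Sequence[Sequence[int]] | np.ndarray],
) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-square for stratified 2x2 tables.

    Classical 1-df CMH statistic without continuity correction. Strata with
    a zero row or column margin carry no information about the conditional
    association and are skipped with a warning.
    """
    usable: list[np.ndarray] = []
    for k, table in enumerate(strata):
        arr = np.asarray(table, dtype=float)
        if arr.shape != (2, 2):
            raise ValueError(f"stratum {k} is not 2x2")
        if _is_degenerate(arr):
            logger.warning("skipping degenerate stratum %d", k)
            continue
        usable.append(arr)
    if not usable:
        raise ValueError("no non-degenerate strata")
    result = StratifiedTable(usable).test_null_odds(correction=False)
    return float(result.statistic), float(result.pvalue)
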