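"""Diagnostic-accuracy evaluation of binary tests against follow-up outcome.

Cytology categories (1 negative, 2 doubtful, 3 suspicious, 4 positive) are
dichotomized as 1 -> negative, 2-4 -> positive.  Confusion tables against the
follow-up outcome yield sensitivity, specificity, PPV and NPV with exact
(Clopper-Pearson) 95% binomial confidence intervals — the exact method is the
only one that produces nondegenerate bounds when a proportion is 0 or 1, as
happens for a test with zero false negatives.

A dichotomous test has a single ROC operating point; the area under its ROC
(the polygon through (0,0), (1-specificity, sensitivity), (1,1)) is
(sensitivity + specificity) / 2, with a Hanley-McNeil standard-error CI.
Two tests evaluated on the same cases are compared with a DeLong-type
correlated-AUC chi-square test on the paired binary scores.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortValidationError

__all__ = [
    "ConfusionTable",
    "Proportion",
    "DiagnosticMetrics",
    "dichotomize_cytology",
    "confusion_from_cohort",
    "clopper_pearson",
    "metrics",
    "binary_auc",
    "compare_auc",
    "round_half_up",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of a binary test against the reference outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise CohortValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_outcome_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_outcome_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class Proportion:
    """Point estimate with a confidence interval (None when undefined)."""

    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    numerator: int = 0
    denominator: int = 0


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    auc: Proportion


def dichotomize_cytology(category: int) -> str:
    """Collapse the four cytology categories to a binary result.

    Category 1 (negative for tumor cells) -> 'negative'; categories 2-4
    (doubtful, suspicious, positive) -> 'positive'.
    """
    if category not in (1, 2, 3, 4):
        raise CohortValidationError(f"cytology category {category!r} not in 1..4")
    return "negative" if category == 1 else "positive"


def _binary_scores(cohort: pd.DataFrame, test: str) -> tuple[np.ndarray, np.ndarray]:
    """(test score in {0,1}, outcome in {0,1}) per case, with validation."""
    for col in ("followup", "cytology" if test == "cytology" else "icm"):
        if col not in cohort.columns:
            raise CohortValidationError(f"cohort is missing the {col!r} column")
        if cohort[col].isna().any():
            raise CohortValidationError(f"cohort has missing values in {col!r}")
    if test == "cytology":
        score = np.array(
            [1 if dichotomize_cytology(int(c)) == "positive" else 0 for c in cohort["cytology"]]
        )
    elif test == "icm":
        bad = set(cohort["icm"]) - {"aneuploid", "non_aneuploid"}
        if bad:
            raise CohortValidationError(f"unknown icm labels: {sorted(bad)}")
        score = (cohort["icm"] == "aneuploid").to_numpy().astype(int)
    else:
        raise CohortValidationError(f"unknown test {test!r}")
    bad = set(cohort["followup"]) - {"positive", "negative"}
    if bad:
        raise CohortValidationError(f"unknown follow-up labels: {sorted(bad)}")
    outcome = (cohort["followup"] == "positive").to_numpy().astype(int)
    return score, outcome


def confusion_from_cohort(cohort: pd.DataFrame, test: str) -> ConfusionTable:
    """Cross-tabulate a test ('cytology' or 'icm') against follow-up outcome."""
    if len(cohort) == 0:
        return ConfusionTable(0, 0, 0, 0)
    score, outcome = _binary_scores(cohort, test)
    return ConfusionTable(
        tp=int(np.sum((score == 1) & (outcome == 1))),
        fp=int(np.sum((score == 1) & (outcome == 0))),
        fn=int(np.sum((score == 0) & (outcome == 1))),
        tn=int(np.sum((score == 0) & (outcome == 0))),
    )


def clopper_pearson(k: int, n: int, ci_level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if n == 0:
        raise CohortValidationError("Clopper-Pearson interval needs n > 0")
    alpha = 1.0 - ci_level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _proportion(k: int, n: int, ci_level: float) -> Proportion:
    if n == 0:
        return Proportion(None, None, None, k, n)
    low, high = clopper_pearson(k, n, ci_level)
    return Proportion(k / n, low, high, k, n)


def metrics(table: ConfusionTable, ci_level: float = 0.95) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and binary AUC with 95% CIs.

    Proportions get exact Clopper-Pearson intervals; a metric with a zero
    denominator is reported as undefined (None), never as 0.
    """
    t = table
    return DiagnosticMetrics(
        sensitivity=_proportion(t.tp, t.tp + t.fn, ci_level),
        specificity=_proportion(t.tn, t.tn + t.fp, ci_level),
        ppv=_proportion(t.tp, t.tp + t.fp, ci_level),
        npv=_proportion(t.tn, t.tn + t.fn, ci_level),
        auc=binary_auc(t, ci_level),
    )


def binary_auc(table: ConfusionTable, ci_level: float = 0.95) -> Proportion:
    """AUC of a one-threshold ROC: (sensitivity + specificity) / 2.

    Equals the trapezoidal area of the ROC polygon through (0, 0),
    (1 - specificity, sensitivity), (1, 1) — and the empirical rank AUC of
    the binary scores.  The CI uses the Hanley-McNeil standard error on the
    numbers of outcome-positive and outcome-negative cases.
    """
    npos, nneg = table.n_outcome_positive, table.n_outcome_negative
    if npos == 0 or nneg == 0:
        return Proportion(None, None, None, 0, table.total)
    se_ = table.tp / npos
    sp_ = table.tn / nneg
    auc = (se_ + sp_) / 2.0
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (npos - 1) * (q1 - auc**2) + (nneg - 1) * (q2 - auc**2)) / (
        npos * nneg
    )
    z = stats.norm.ppf(1 - (1 - ci_level) / 2)
    half = z * np.sqrt(max(var, 0.0))
    return Proportion(auc, max(0.0, auc - half), min(1.0, auc + half), 0, table.total)


def _delong_components(score: np.ndarray, outcome: np.ndarray):
    """Placement values (V10 per positive case, V01 per negative case)."""
    x = score[outcome == 1].astype(float)
    y = score[outcome == 0].astype(float)
    v10 = np.array([np.mean(y < xi) + 0.5 * np.mean(y == xi) for xi in x])
    v01 = np.array([np.mean(x > yj) + 0.5 * np.mean(x == yj) for yj in y])
    return v10, v01


def compare_auc(
    table_a: ConfusionTable,
    table_b: ConfusionTable,
    paired_cohort: pd.DataFrame,
    test_a: str = "cytology",
    test_b: str = "icm",
) -> dict:
    """DeLong-type chi-square test for two correlated (paired) binary AUCs.

    Both tests must be evaluated on the same cases; ``paired_cohort`` carries
    the per-case results, and the supplied tables are checked against it.
    Returns {'auc_a', 'auc_b', 'statistic', 'df', 'p_value'}.
    """
    score_a, outcome = _binary_scores(paired_cohort, test_a)
    score_b, outcome_b = _binary_scores(paired_cohort, test_b)
    if not np.array_equal(outcome, outcome_b):
        raise CohortValidationError("tests are not paired on the same cases")
    for table, score, name in ((table_a, score_a, test_a), (table_b, score_b, test_b)):
        found = confusion_from_cohort(paired_cohort, name)
        if found != table:
            raise CohortValidationError(
                f"confusion table for {name!r} does not match the paired cohort"
            )
    m, n = int(outcome.sum()), int((1 - outcome).sum())
    if m == 0 or n == 0:
        raise CohortValidationError("need both outcome-positive and -negative cases")

    v10a, v01a = _delong_components(score_a, outcome)
    v10b, v01b = _delong_components(score_b, outcome)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if abs(diff) < 1e-15:
        statistic, p = 0.0, 1.0
    elif var_diff <= 0:
        statistic, p = float("inf"), 0.0
    else:
        statistic = diff**2 / var_diff
        p = float(stats.chi2.sf(statistic, df=1))
    return {"auc_a": auc_a, "auc_b": auc_b, "statistic": float(statistic), "df": 1, "p_value": p}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed clinical tables."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
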