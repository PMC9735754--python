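"""Logistic regression on grouped cohort counts, with separation surfaced.

The study design produces grouped binomial data: a handful of covariate
patterns (cytology positive/negative x ploidy aneuploid/non-aneuploid), each
with a number of follow-up-positive cases out of a total.  The maximum
likelihood fit is computed by Newton/IRLS written out in this module so that
its failure mode under complete or quasi-complete separation — a covariate
pattern with an all-or-none outcome — is detected and reported rather than
silently truncated at whatever iterate the optimizer stopped on.  A cohort
with zero false-negative cytology, for example, makes the cytology
coefficient's likelihood monotone: its MLE is +infinity and any finite
"estimate" is an artifact of the stopping rule.

What remains identifiable in such designs is the conditional (stratum-wise)
odds ratio, computed in closed form as the cross-product ratio with a Wald
interval on the log scale.  A Firth bias-reduced fit (Jeffreys-prior
penalty), which is finite under separation, is provided as a clearly
labelled alternative, not as the default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import expit

from .errors import CohortValidationError, ModelError

__all__ = [
    "Pattern",
    "GroupedCohort",
    "LogisticFit",
    "fit_logistic_grouped",
    "fit_logistic_firth",
    "conditional_odds_ratio",
    "grouped_cohort_from_frame",
]

MAX_ITER = 100
TOL = 1e-8
SEPARATION_BOUND = 15.0  # |log-odds| beyond this while deviance still falls


@dataclass(frozen=True)
class Pattern:
    """One covariate pattern: binary predictors plus outcome counts."""

    cytology: int  # 1 = dichotomized positive, 0 = negative
    icm: int  # 1 = aneuploid, 0 = non-aneuploid
    n_positive_outcome: int
    n_total: int

    def __post_init__(self):
        if self.n_total <= 0:
            raise CohortValidationError("each pattern needs n_total > 0")
        if not 0 <= self.n_positive_outcome <= self.n_total:
            raise CohortValidationError("0 <= n_positive_outcome <= n_total violated")


@dataclass
class GroupedCohort:
    patterns: list[Pattern]

    @property
    def n_total(self) -> int:
        return sum(p.n_total for p in self.patterns)


@dataclass
class LogisticFit:
    predictors: list[str]
    coefficients: dict  # name -> log-odds (None when non-identifiable)
    odds_ratios: dict  # name -> OR (math.inf / None when separated)
    wald_ci: dict  # name -> (low, high) or None
    converged: bool
    separation: list[str] = field(default_factory=list)
    deviance: Optional[float] = None
    deviance_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    notes: list[str] = field(default_factory=list)


def grouped_cohort_from_frame(cohort) -> GroupedCohort:
    """Collapse a per-case cohort table into grouped covariate patterns."""
    from .diagnostics import dichotomize_cytology

    df = cohort.copy()
    df["cyt_bin"] = [
        1 if dichotomize_cytology(int(c)) == "positive" else 0 for c in df["cytology"]
    ]
    df["icm_bin"] = (df["icm"] == "aneuploid").astype(int)
    df["out"] = (df["followup"] == "positive").astype(int)
    patterns = []
    for (cyt, icm), grp in df.groupby(["cyt_bin", "icm_bin"], sort=True):
        patterns.append(
            Pattern(
                cytology=int(cyt),
                icm=int(icm),
                n_positive_outcome=int(grp["out"].sum()),
                n_total=int(len(grp)),
            )
        )
    return GroupedCohort(patterns=patterns)


def _predictor_column(cohort: GroupedCohort, name: str) -> np.ndarray:
    # "a:b" denotes the product (interaction) of two binary predictors
    parts = name.split(":")
    col = np.ones(len(cohort.patterns))
    for part in parts:
        col = col * np.array([getattr(p, part) for p in cohort.patterns], dtype=float)
    return col


def _design(cohort: GroupedCohort, predictors: list[str]):
    if not predictors:
        raise ModelError("at least one predictor is required")
    X = np.column_stack(
        [np.ones(len(cohort.patterns))]
        + [_predictor_column(cohort, name) for name in predictors]
    )
    y = np.array([p.n_positive_outcome for p in cohort.patterns], dtype=float)
    n = np.array([p.n_total for p in cohort.patterns], dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("design matrix is rank deficient")
    return X, y, n


def _deviance(y, n, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - mu)), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


def fit_logistic_grouped(cohort: GroupedCohort, predictors: list[str]) -> LogisticFit:
    """Maximum-likelihood logistic fit on grouped binomial counts (IRLS).

    Newton/IRLS with convergence when the largest coefficient change falls
    below 1e-8, capped at 100 iterations.  Separation is declared when a
    coefficient's magnitude exceeds 15 on the log-odds scale while the
    deviance is still decreasing monotonically; the affected coefficient is
    then reported as unbounded (OR = inf or 0) rather than as a finite
    number, and no Wald interval is given for it.
    """
    X, y, n = _design(cohort, predictors)
    names = ["intercept"] + list(predictors)
    beta = np.zeros(X.shape[1])
    deviances = []
    converged = False
    separated_idx: list[int] = []
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        p = expit(eta)
        mu = n * p
        w = n * p * (1 - p)
        # Fisher scoring step; tiny ridge keeps the solve stable as the
        # weights collapse under separation
        xtw = X.T * w
        h = xtw @ X + 1e-12 * np.eye(X.shape[1])
        step = np.linalg.solve(h, X.T @ (y - mu))
        beta = beta + step
        deviances.append(_deviance(y, n, n * expit(X @ beta)))
        if np.max(np.abs(step)) < TOL:
            converged = True
            break
        monotone = all(b <= a + 1e-9 for a, b in zip(deviances, deviances[1:]))
        if monotone and np.max(np.abs(beta)) > SEPARATION_BOUND:
            # monotone likelihood: the diverging coefficients are those still
            # taking O(1) steps every iteration; stop before the collapsing
            # weights turn the solve into noise
            separated_idx = [
                j
                for j in range(len(beta))
                if abs(beta[j]) > SEPARATION_BOUND or abs(step[j]) > 0.1
            ]
            break
    separated = [names[j] for j in separated_idx]

    # Wald covariance at the final iterate (meaningless for separated terms)
    p = expit(X @ beta)
    w = n * p * (1 - p)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)

    z = stats.norm.ppf(0.975)
    coefficients, odds_ratios, wald_ci = {}, {}, {}
    notes = []
    for j, name in enumerate(names):
        if name in separated:
            coefficients[name] = None
            odds_ratios[name] = float("inf") if beta[j] > 0 else 0.0
            wald_ci[name] = None
            notes.append(
                f"{name}: monotone likelihood (separation); MLE unbounded, "
                "no finite estimate or Wald interval exists"
            )
        else:
            se = float(np.sqrt(cov[j, j]))
            coefficients[name] = float(beta[j])
            odds_ratios[name] = float(np.exp(beta[j]))
            wald_ci[name] = (
                float(np.exp(beta[j] - z * se)),
                float(np.exp(beta[j] + z * se)),
            )
    return LogisticFit(
        predictors=list(predictors),
        coefficients=coefficients,
        odds_ratios=odds_ratios,
        wald_ci=wald_ci,
        converged=converged and not separated,
        separation=separated,
        deviance=deviances[-1] if deviances else None,
        deviance_trace=deviances,
        n_iterations=it,
        notes=notes,
    )


def fit_logistic_firth(cohort: GroupedCohort, predictors: list[str]) -> LogisticFit:
    """Firth bias-reduced logistic fit (Jeffreys-prior penalty).

    Finite even under separation; provided as a labelled alternative for
    separated designs, not as the default estimator.
    """
    X, y, n = _design(cohort, predictors)
    names = ["intercept"] + list(predictors)
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        p = expit(X @ beta)
        w = n * p * (1 - p)
        xtw = X.T * w
        info = xtw @ X + 1e-12 * np.eye(X.shape[1])
        info_inv = np.linalg.inv(info)
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None] ** 0.5, info_inv, X * w[:, None] ** 0.5)
        score = X.T @ (y - n * p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < TOL:
            converged = True
            break

    p = expit(X @ beta)
    w = n * p * (1 - p)
    cov = np.linalg.inv((X.T * w) @ X)
    z = stats.norm.ppf(0.975)
    coefficients = {name: float(beta[j]) for j, name in enumerate(names)}
    odds_ratios = {name: float(np.exp(beta[j])) for j, name in enumerate(names)}
    wald_ci = {
        name: (
            float(np.exp(beta[j] - z * np.sqrt(cov[j, j]))),
            float(np.exp(beta[j] + z * np.sqrt(cov[j, j]))),
        )
        for j, name in enumerate(names)
    }
    return LogisticFit(
        predictors=list(predictors),
        coefficients=coefficients,
        odds_ratios=odds_ratios,
        wald_ci=wald_ci,
        converged=converged,
        separation=[],
        deviance=_deviance(y, n, n * expit(X @ beta)),
        n_iterations=it,
        notes=["Firth bias-reduced (penalized) estimates, not maximum likelihood"],
    )


def conditional_odds_ratio(
    cohort: GroupedCohort,
    predictor: str,
    stratum: Optional[dict] = None,
    ci_level: float = 0.95,
    continuity: bool = False,
) -> dict:
    """Closed-form odds ratio for one binary predictor within a stratum.

    Aggregates the stratum's 2x2 table (predictor x outcome) and returns the
    cross-product ratio OR = (a/b)/(c/d) with the Wald interval
    exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  A zero cell makes the
    OR undefined unless ``continuity`` adds 0.5 to all four cells
    (Haldane-Anscombe correction).
    """
    stratum = stratum or {}
    a = b = c = d = 0.0
    for p in cohort.patterns:
        if any(getattr(p, k) != v for k, v in stratum.items()):
            continue
        if getattr(p, predictor) == 1:
            a += p.n_positive_outcome
            b += p.n_total - p.n_positive_outcome
        else:
            c += p.n_positive_outcome
            d += p.n_total - p.n_positive_outcome
    cells = {"a": a, "b": b, "c": c, "d": d}
    if min(a, b, c, d) == 0:
        if not continuity:
            return {"or": None, "ci": None, "cells": cells,
                    "note": "zero cell; OR undefined without continuity correction"}
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log((a / b) / (c / d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - (1 - ci_level) / 2)
    return {
        "or": float(np.exp(log_or)),
        "ci": (float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))),
        "cells": cells,
    }
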