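"""Diagnostic accuracy, association tests, and the per-point logistic risk model.

Cross-classifies the baseline impaired/normal call against the PSCI outcome,
computes sensitivity / specificity / PPV / NPV with the half-up percent
rendering used in clinical tables, Pearson chi-square association, group
comparisons (t-test / chi-square), and a logistic model whose odds ratio is
reported per point of MoCA *lost* (lower score -> higher PSCI risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ContingencyTable2x2",
    "AccuracyIndices",
    "LogisticRiskFit",
    "GroupComparison",
    "build_contingency",
    "accuracy_indices",
    "pearson_chi2",
    "fit_logistic",
    "proportion",
    "compare_groups",
]

#: coefficient magnitude beyond which the logistic fit is treated as separated
SEPARATION_COEF_LIMIT = 50.0


def proportion(count: int, total: int, decimals: int = 0) -> float:
    """100*count/total rounded half-up to `decimals` (the clinical-table "n (x%)" cell).

    Half-up (not banker's) rounding: 46.75 -> 47 at 0 decimals.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    pct = Decimal(100 * count) / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at `decimals`, as clinical tables do."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts cross-classifying baseline impaired/normal vs PSCI yes/no.

    tp = impaired & PSCI, fp = impaired & no PSCI,
    fn = normal & PSCI,   tn = normal & no PSCI.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """Rows: impaired, normal. Columns: PSCI, no PSCI."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=float)


@dataclass(frozen=True)
class AccuracyIndices:
    """Se/Sp/PPV/NPV as exact proportions; None where the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_percents(self, decimals: int = 0) -> dict[str, float | None]:
        return {
            k: None if v is None else round_half_up(100 * v, decimals)
            for k, v in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


@dataclass(frozen=True)
class LogisticRiskFit:
    """Per-point logistic risk of PSCI on the adjusted baseline MoCA score.

    `coefficient` is the log-odds change per one-point *increase* of the
    adjusted score; `odds_ratio_per_point_lost` = exp(-coefficient) reports
    the clinically natural direction (risk multiplier per point lost).
    """

    coefficient: float
    intercept: float
    odds_ratio_per_point_lost: float
    ci95: tuple[float, float]
    n: int
    converged: bool
    message: str = ""


def build_contingency(
    performances: Sequence[str], outcomes: Sequence[bool]
) -> ContingencyTable2x2:
    """Cross-classify impaired/normal calls against PSCI booleans."""
    if len(performances) != len(outcomes):
        raise ValueError(
            f"length mismatch: {len(performances)} performances vs {len(outcomes)} outcomes"
        )
    if not performances:
        raise ValueError("empty input")
    tp = fp = fn = tn = 0
    for perf, psci in zip(performances, outcomes):
        if perf not in ("impaired", "normal"):
            raise ValueError(f"performance must be 'impaired' or 'normal', got {perf!r}")
        if perf == "impaired":
            tp += bool(psci)
            fp += not psci
        else:
            fn += bool(psci)
            tn += not psci
    return ContingencyTable2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy_indices(table: ContingencyTable2x2) -> AccuracyIndices:
    """Se = tp/(tp+fn), Sp = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn).

    An index whose denominator is zero is returned as None ("undefined"),
    never coerced to 0 or 1.
    """
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return AccuracyIndices(
        sensitivity=ratio(table.tp, table.tp + table.fn),
        specificity=ratio(table.tn, table.tn + table.fp),
        ppv=ratio(table.tp, table.tp + table.fp),
        npv=ratio(table.tn, table.tn + table.fn),
    )


def pearson_chi2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("a zero marginal makes the chi-square inestimable")
    stat, p, _, _ = scipy.stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fit_logistic(
    adjusted_values: Sequence[float],
    outcomes: Sequence[bool],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticRiskFit:
    """Maximum-likelihood fit of logit P(PSCI) = intercept + coefficient * adjusted.

    The Wald 95% CI is reported on the per-point-lost odds-ratio scale.
    Separation or non-convergence yields ``converged=False`` with a message
    rather than an exception.
    """
    x = np.asarray(adjusted_values, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("adjusted_values and outcomes must be equal-length 1-D")
    n = len(x)
    if n < 10:
        raise ValueError(f"need n >= 10 observations, got {n}")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    X = sm.add_constant(x)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=max_iter, tol=tol)
        intercept, coef = res.params
        se = res.bse[1]
        converged = bool(res.mle_retvals.get("converged", True))
        message = ""
    except Exception as exc:  # perfect separation raises inside statsmodels
        return LogisticRiskFit(
            coefficient=math.nan, intercept=math.nan,
            odds_ratio_per_point_lost=math.nan, ci95=(math.nan, math.nan),
            n=n, converged=False, message=f"fit failed: {exc}",
        )
    if abs(coef) > SEPARATION_COEF_LIMIT or se > SEPARATION_COEF_LIMIT or not converged:
        converged = False
        message = "apparent separation or non-convergence; estimates unreliable"

    # OR per point LOST: exp(-coef); CI endpoints swap and invert accordingly
    def _exp(v: float) -> float:
        return math.exp(v) if v < 700 else math.inf

    or_lost = _exp(-coef)
    z = scipy.stats.norm.ppf(0.975)
    ci = (_exp(-coef - z * se), _exp(-coef + z * se))
    return LogisticRiskFit(
        coefficient=float(coef), intercept=float(intercept),
        odds_ratio_per_point_lost=or_lost, ci95=(min(ci), max(ci)),
        n=n, converged=converged, message=message,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-group baseline comparison: summaries plus the two-sided p-value."""

    variable: str
    kind: str  # "t" or "chi2"
    summary_a: str
    summary_b: str
    statistic: float
    p: float


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variable: str = "",
    kind: str = "auto",
    equal_var: bool = True,
) -> GroupComparison:
    """Compare one baseline variable between two sub-cohorts.

    Numeric variables get a pooled-variance two-sided t-test (Welch via
    ``equal_var=False``) and are summarised "mean ± SD"; binary 0/1
    variables get a Pearson chi-square on the 2x2 count table and are
    summarised "n (x%)".
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "auto":
        kind = "chi2" if set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0} else "t"

    if kind == "t":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("zero variance in both groups: t-test inestimable")
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
        summ_a = f"{a.mean():.1f} ± {a.std(ddof=1):.1f}"
        summ_b = f"{b.mean():.1f} ± {b.std(ddof=1):.1f}"
    elif kind == "chi2":
        counts = np.array(
            [[a.sum(), a.size - a.sum()], [b.sum(), b.size - b.sum()]], dtype=float
        )
        if (counts.sum(axis=0) == 0).any():
            raise ValueError("a zero marginal makes the chi-square inestimable")
        stat, p, _, _ = scipy.stats.chi2_contingency(counts, correction=False)
        summ_a = f"{int(a.sum())} ({proportion(int(a.sum()), a.size):.0f}%)"
        summ_b = f"{int(b.sum())} ({proportion(int(b.sum()), b.size):.0f}%)"
    else:
        raise ValueError(f"kind must be 't', 'chi2' or 'auto', got {kind!r}")
    return GroupComparison(
        variable=variable, kind=kind, summary_a=summ_a, summary_b=summ_b,
        statistic=float(stat), p=float(p),
    )


def format_p(p: float, threshold: float = 0.001) -> str:
    """Render a p-value the way clinical tables print it ('<0.001' below threshold)."""
    return f"<{threshold:g}" if p < threshold else f"{p:.3f}"
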