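"""ROC analysis of adjusted baseline MoCA against PSCI and optimal cut-off selection.

Orientation: lower MoCA means worse cognition, so a patient tests *positive*
when the adjusted score is strictly below the threshold. Candidate
thresholds are the midpoints between consecutive distinct observed values
plus sentinels below the minimum and above the maximum — the reported
optimal cut-offs therefore fall *between* patients' scores, which is how
non-observed values such as 22.82 arise in screening tables.

The adequacy rule for a screening cut-off is Se >= 0.80 and Sp >= 0.60;
among adequate thresholds the one maximizing Youden's J (= Se + Sp - 1) is
selected, preferring higher sensitivity and then the lower threshold on
ties. When no threshold is adequate, the global Youden maximizer is
returned flagged inadequate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import round_half_up

__all__ = ["RocPoint", "RocCurve", "CutpointResult", "roc_points", "auc", "threshold_table", "select_optimal"]


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class RocCurve:
    """Ordered (threshold, Se, Sp) coordinates plus trapezoidal AUC.

    Thresholds are strictly decreasing; under the "positive iff score <
    threshold" orientation sensitivity is then non-increasing and
    specificity non-decreasing along the list.
    """

    points: tuple[RocPoint, ...]
    auc: float
    n_pos: int
    n_neg: int
    dataset: str = ""
    orientation: str = "positive test iff adjusted score < threshold"


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    youden: float
    adequate: bool


def roc_points(
    adjusted_values: Sequence[float],
    outcomes: Sequence[bool],
    dataset: str = "",
) -> RocCurve:
    """Build the full ROC curve of adjusted score vs PSCI truth.

    Thresholds are midpoints of consecutive distinct scores with sentinels
    (min - 1) and (max + 1); every (Se, Sp) pair is an exact recount of the
    cohort at that threshold.
    """
    x = np.asarray(adjusted_values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("adjusted_values and outcomes must be equal-length 1-D")
    if len(x) < 4:
        raise ValueError(f"need n >= 4 patients, got {len(x)}")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])

    pts = []
    for t in thresholds[::-1]:  # strictly decreasing thresholds
        positive = x < t
        se = float((positive & y).sum() / n_pos)
        sp = float((~positive & ~y).sum() / n_neg)
        pts.append(RocPoint(threshold=float(t), sensitivity=se, specificity=sp))

    return RocCurve(points=tuple(pts), auc=_trapezoid_auc(pts),
                    n_pos=n_pos, n_neg=n_neg, dataset=dataset)


def _trapezoid_auc(points: Sequence[RocPoint]) -> float:
    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    order = np.lexsort((tpr, fpr))  # ties in FPR ascend in TPR
    return float(np.trapezoid(tpr[order], fpr[order]))


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under (1 - Sp, Se).

    Equals the concordance probability P(score_PSCI < score_noPSCI) +
    0.5 * P(tie), i.e. the Mann-Whitney statistic.
    """
    return curve.auc


def threshold_table(
    curve: RocCurve,
    around: tuple[float, float] | None = None,
    decimals: int = 0,
) -> pd.DataFrame:
    """Tabulate (threshold, Se%, Sp%) rows ordered by threshold, optimal row flagged.

    `around` restricts to thresholds inside [low, high]. Percentages are
    rounded half-up; the `optimal` column flags the selected cut-off.
    """
    best = select_optimal(curve)
    rows = []
    for p in sorted(curve.points, key=lambda p: p.threshold):
        if around is not None and not (around[0] <= p.threshold <= around[1]):
            continue
        rows.append({
            "threshold": p.threshold,
            "sensitivity_pct": round_half_up(100 * p.sensitivity, decimals),
            "specificity_pct": round_half_up(100 * p.specificity, decimals),
            "optimal": math.isclose(p.threshold, best.threshold),
        })
    return pd.DataFrame(rows, columns=["threshold", "sensitivity_pct", "specificity_pct", "optimal"])


def select_optimal(
    curve: RocCurve, min_se: float = 0.80, min_sp: float = 0.60
) -> CutpointResult:
    """Select the screening cut-off under the adequacy criterion.

    Among thresholds with Se >= min_se and Sp >= min_sp, maximize Youden's
    J; ties prefer higher sensitivity (screening misses are the costlier
    error), then the lower threshold. If none qualifies, return the global
    Youden maximizer with ``adequate=False``.
    """
    adequate = [p for p in curve.points
                if p.sensitivity >= min_se and p.specificity >= min_sp]
    pool, is_adequate = (adequate, True) if adequate else (list(curve.points), False)
    best = max(pool, key=lambda p: (p.youden, p.sensitivity, -p.threshold))

    # PPV/NPV at the chosen threshold from the class sizes
    tp = best.sensitivity * curve.n_pos
    fn = curve.n_pos - tp
    tn = best.specificity * curve.n_neg
    fp = curve.n_neg - tn
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    return CutpointResult(
        threshold=best.threshold, sensitivity=best.sensitivity,
        specificity=best.specificity, ppv=ppv, npv=npv,
        youden=best.youden, adequate=is_adequate,
    )
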