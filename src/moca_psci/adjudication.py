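"""Adjudication of 6-9 month cognitive outcome: none / MCI / dementia.

A followed-up patient is cognitively impaired when at least one
neuropsychological test in the follow-up battery is impaired (its
demographically adjusted score falls below the 5th centile of the normal
population; the per-test norming happens upstream and arrives here as
boolean flags). The MCI/dementia split rests on functional dependence in
ADL or IADL, counted only when that dependence is cognitive in origin —
dependence attributable to motor/sensory sequelae of the stroke, or to
another disease, does not make a dementia.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

__all__ = [
    "TestResult",
    "FollowUpAssessment",
    "PsciDiagnosis",
    "NotAssessableError",
    "flag_cognitive_impairment",
    "adjudicate",
    "outcome_table",
]

Domain = Literal["memory", "attention_executive", "language", "visuospatial"]
Category = Literal["none", "mci", "dementia"]


class NotAssessableError(ValueError):
    """The follow-up assessment has no test results and cannot be adjudicated."""


@dataclass(frozen=True)
class TestResult:
    test_name: str
    domain: Domain
    impaired: bool


@dataclass(frozen=True)
class FollowUpAssessment:
    """Per-test impairment flags plus functional status for one followed-up patient."""

    patient_id: str
    test_results: tuple[TestResult, ...]
    adl_dependent: bool
    iadl_dependent: bool
    mrs: int | None = None  # descriptive only; plays no role in adjudication
    functional_loss_noncognitive: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "test_results", tuple(self.test_results))
        if self.mrs is not None and not 0 <= self.mrs <= 6:
            raise ValueError(f"mRS must be in [0, 6], got {self.mrs}")


@dataclass(frozen=True)
class PsciDiagnosis:
    patient_id: str
    category: Category

    @property
    def psci(self) -> bool:
        return self.category != "none"


def flag_cognitive_impairment(assessment: FollowUpAssessment) -> bool:
    """True iff at least one test in the battery is impaired."""
    if not assessment.test_results:
        raise NotAssessableError(
            f"patient {assessment.patient_id}: no test results at follow-up"
        )
    return any(t.impaired for t in assessment.test_results)


def adjudicate(assessment: FollowUpAssessment) -> PsciDiagnosis:
    """Map one follow-up assessment to none / MCI / dementia.

    dementia requires cognitive impairment AND dependence in ADL or IADL
    AND that the dependence is not attributable to motor/sensory sequelae
    or other non-cognitive causes; cognitive impairment without qualifying
    dependence is MCI; no impaired test is no PSCI.
    """
    if not flag_cognitive_impairment(assessment):
        return PsciDiagnosis(assessment.patient_id, "none")
    dependent = assessment.adl_dependent or assessment.iadl_dependent
    if dependent and not assessment.functional_loss_noncognitive:
        return PsciDiagnosis(assessment.patient_id, "dementia")
    return PsciDiagnosis(assessment.patient_id, "mci")


def outcome_table(diagnoses: Iterable[PsciDiagnosis]) -> dict[Category, int]:
    """Counts of none/MCI/dementia; always contains all three keys."""
    diagnoses = list(diagnoses)
    if not diagnoses:
        raise ValueError("no diagnoses supplied")
    counts = Counter(d.category for d in diagnoses)
    return {"none": counts["none"], "mci": counts["mci"], "dementia": counts["dementia"]}
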