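"""Demographic adjustment of raw MoCA totals under three Italian normative datasets.

Each normative dataset publishes a regression-based correction of the raw
MoCA total (0-30) for age and years of education, together with the
equivalent-score ES=0 cut-off: an adjusted score strictly below the cut-off
is an *impaired* performance (below the outer tolerance limit of the normal
population's 5th centile); at or above it the performance is *normal*.

The three correction equations, evaluated at (possibly clamped) demographics:

    conti:      adj = raw + 0.175*(age - 70.08) + 24.3*(1/edu - 0.126)
    santangelo: adj = raw - 4.228*(log10(100 - age) - 1.58) - 3.201*(sqrt(edu) - 3.25)
    aiello:     adj = raw + 0.000008*(age^3 - 297697.184801) - 3.331407*(ln(edu) - 2.325648)

Adjusted values are deliberately not clamped to [0, 30]: the corrections are
smooth additive terms and clamping would distort the ordering that the ROC
analysis depends on.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal

__all__ = [
    "PatientRecord",
    "NormativeDataset",
    "AdjustedScore",
    "NORMATIVE_DATASETS",
    "get_dataset",
    "adjust_score",
    "classify_performance",
    "adjust_cohort",
    "impairment_rate",
    "ScoreUnavailableError",
]

logger = logging.getLogger(__name__)

DatasetName = Literal["conti", "santangelo", "aiello"]
Performance = Literal["impaired", "normal"]

#: education (years) substituted when 0 is supplied; 1/edu and ln(edu) are
#: undefined at zero and the normative samples contain no illiterate subjects
DEFAULT_MIN_EDUCATION = 1.0
#: Santangelo's log10(100 - age) is undefined for age >= 100
MAX_AGE_SANTANGELO = 99.0


class ScoreUnavailableError(ValueError):
    """Raised when an operation needs a raw MoCA total that is missing."""


@dataclass(frozen=True)
class PatientRecord:
    """One enrolled subject: demographics, index event, baseline MoCA, follow-up linkage."""

    id: str
    age: float
    education_years: float
    sex: Literal["female", "male"]
    event_type: Literal["TIA", "ischemic", "hemorrhagic"]
    nihss: int | None = None
    moca_raw: int | None = None
    followed_up: bool = False
    follow_up_months: float | None = None
    centre: str | None = None

    def __post_init__(self) -> None:
        if not self.age > 18:
            raise ValueError(f"age must exceed 18 years, got {self.age}")
        if self.education_years < 0:
            raise ValueError(f"education_years must be >= 0, got {self.education_years}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.event_type not in ("TIA", "ischemic", "hemorrhagic"):
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.nihss is not None and not (0 <= self.nihss <= 42):
            raise ValueError(f"nihss must be in [0, 42], got {self.nihss}")
        if self.moca_raw is not None:
            _validate_raw(self.moca_raw)
        if self.followed_up and self.follow_up_months is None:
            raise ValueError("followed_up patients need follow_up_months")
        if not self.followed_up and self.follow_up_months is not None:
            raise ValueError("follow_up_months given for a patient without follow-up")
        if self.follow_up_months is not None and self.follow_up_months < 0:
            raise ValueError("follow_up_months must be >= 0")


@dataclass(frozen=True)
class NormativeDataset:
    """One normative system: equation constants, age range, ES=0 cut-off."""

    name: DatasetName
    es0_cutoff: float
    age_range: tuple[float, float]
    age_slope: float
    age_center: float
    edu_slope: float
    edu_center: float

    def adjust(self, raw: float, age: float, education_years: float) -> float:
        """Evaluate the published correction equation (no clamping, no checks)."""
        if self.name == "conti":
            return (
                raw
                + self.age_slope * (age - self.age_center)
                + self.edu_slope * (1.0 / education_years - self.edu_center)
            )
        if self.name == "santangelo":
            return (
                raw
                - self.age_slope * (math.log10(100.0 - age) - self.age_center)
                - self.edu_slope * (math.sqrt(education_years) - self.edu_center)
            )
        # aiello
        return (
            raw
            + self.age_slope * (age**3 - self.age_center)
            - self.edu_slope * (math.log(education_years) - self.edu_center)
        )


def _load_datasets() -> dict[str, NormativeDataset]:
    text = resources.files("moca_psci.data").joinpath("normative_datasets.json").read_text("utf-8")
    out: dict[str, NormativeDataset] = {}
    for name, entry in json.loads(text).items():
        c = entry["coefficients"]
        out[name] = NormativeDataset(
            name=name,
            es0_cutoff=entry["es0_cutoff"],
            age_range=tuple(entry["age_range"]),
            age_slope=c["age_slope"],
            age_center=c["age_center"],
            edu_slope=c["edu_slope"],
            edu_center=c["edu_center"],
        )
    return out


NORMATIVE_DATASETS: dict[str, NormativeDataset] = _load_datasets()


def get_dataset(name: str) -> NormativeDataset:
    """Look up a normative dataset by name ('conti', 'santangelo', 'aiello')."""
    try:
        return NORMATIVE_DATASETS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown normative dataset {name!r}; expected one of {sorted(NORMATIVE_DATASETS)}"
        ) from None


@dataclass(frozen=True)
class AdjustedScore:
    """A demographically adjusted MoCA value with its impaired/normal call."""

    patient_id: str
    dataset: DatasetName
    value: float
    performance: Performance
    clamped_inputs: bool = False
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("adjusted value must be finite")


def _validate_raw(raw: object) -> int:
    if raw is None:
        raise ScoreUnavailableError("raw MoCA total is missing")
    if isinstance(raw, bool) or not float(raw).is_integer():
        raise ValueError(f"raw MoCA total must be an integer, got {raw!r}")
    raw = int(raw)
    if not 0 <= raw <= 30:
        raise ValueError(f"raw MoCA total must be in [0, 30], got {raw}")
    return raw


def adjust_score(
    raw: int,
    age: float,
    education_years: float,
    dataset: NormativeDataset | str,
    *,
    min_education: float = DEFAULT_MIN_EDUCATION,
    patient_id: str = "",
) -> AdjustedScore:
    """Adjust a raw MoCA total for age and education under one normative dataset.

    Parameters
    ----------
    raw
        Raw MoCA total, integer in [0, 30]. A missing value raises
        :class:`ScoreUnavailableError` so it can never be confused with a
        numeric result.
    age, education_years
        Demographics in years. Degenerate values that make the equation
        undefined are clamped (education 0 -> ``min_education``; age >= 100 ->
        99 for Santangelo) and the result is flagged ``clamped_inputs``.
        Ages outside the dataset's normative range are evaluated anyway and
        flagged ``extrapolated``.
    dataset
        A :class:`NormativeDataset` or its name.

    Returns
    -------
    AdjustedScore
        With ``performance`` set to ``"impaired"`` iff the adjusted value is
        strictly below the dataset's ES=0 cut-off.
    """
    raw = _validate_raw(raw)
    if not age > 18:
        raise ValueError(f"age must exceed 18 years, got {age}")
    if education_years < 0:
        raise ValueError(f"education_years must be >= 0, got {education_years}")
    if isinstance(dataset, str):
        dataset = get_dataset(dataset)

    clamped = False
    eff_age, eff_edu = float(age), float(education_years)
    if dataset.name in ("conti", "aiello") and eff_edu < min_education:
        logger.warning(
            "education %.2f years undefined for %s equation; clamped to %.2f",
            eff_edu, dataset.name, min_education,
        )
        eff_edu, clamped = min_education, True
    if dataset.name == "santangelo":
        if eff_edu < 0:  # sqrt is defined at 0; only negatives are impossible
            eff_edu, clamped = 0.0, True
        if eff_age > MAX_AGE_SANTANGELO:
            logger.warning("age %.1f undefined for santangelo equation; clamped to 99", eff_age)
            eff_age, clamped = MAX_AGE_SANTANGELO, True

    lo, hi = dataset.age_range
    extrapolated = not (lo <= age <= hi)

    value = dataset.adjust(raw, eff_age, eff_edu)
    return AdjustedScore(
        patient_id=patient_id,
        dataset=dataset.name,
        value=value,
        performance="impaired" if value < dataset.es0_cutoff else "normal",
        clamped_inputs=clamped,
        extrapolated=extrapolated,
    )


def classify_performance(adjusted: AdjustedScore) -> Performance:
    """Impaired iff the adjusted value is strictly below the dataset's ES=0 cut-off."""
    cutoff = get_dataset(adjusted.dataset).es0_cutoff
    return "impaired" if adjusted.value < cutoff else "normal"


def adjust_cohort(
    records: Iterable[PatientRecord],
    dataset: NormativeDataset | str,
    *,
    min_education: float = DEFAULT_MIN_EDUCATION,
) -> list[AdjustedScore]:
    """Adjust every record with a non-missing raw MoCA, preserving input order.

    Records without a baseline MoCA are skipped and logged; an empty input
    cohort is a validation error.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort is empty")
    if isinstance(dataset, str):
        dataset = get_dataset(dataset)
    scores: list[AdjustedScore] = []
    n_skipped = 0
    for rec in records:
        if rec.moca_raw is None:
            n_skipped += 1
            logger.info("patient %s skipped: no baseline MoCA", rec.id)
            continue
        scores.append(
            adjust_score(
                rec.moca_raw, rec.age, rec.education_years, dataset,
                min_education=min_education, patient_id=rec.id,
            )
        )
    if n_skipped:
        logger.warning("%d of %d records had no baseline MoCA and were skipped",
                       n_skipped, len(records))
    return scores


def impairment_rate(scores: list[AdjustedScore], decimals: int = 0) -> tuple[float, float]:
    """Proportion of impaired performances: (exact ratio, half-up rounded percent).

    All scores must come from the same normative dataset.
    """
    from .diagnostics import proportion

    if not scores:
        raise ValueError("no adjusted scores supplied")
    datasets = {s.dataset for s in scores}
    if len(datasets) > 1:
        raise ValueError(f"scores mix normative datasets: {sorted(datasets)}")
    n_imp = sum(s.performance == "impaired" for s in scores)
    return n_imp / len(scores), proportion(n_imp, len(scores), decimals)
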