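"""Symptom-based AKI risk score used for enrollment triage.

Each of the 12 presentation symptoms contributes one point (hypertension
counts only in pregnant women).  Categories: 0–2 low, 3–5 moderate, >=6 high;
only moderate- and high-risk patients are eligible for enrollment.  The
printed thresholds leave a score of exactly 6 between the bands; it is
classified ``high`` by default, switchable via ``score6_category``.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

from .types import SymptomProfile

MAX_SCORE = 12
ELIGIBILITY_THRESHOLD = 3


class RiskCategory(str, enum.Enum):
    low = "low"
    moderate = "moderate"
    high = "high"


@dataclass(frozen=True)
class RiskAssessment:
    score: int
    category: RiskCategory
    eligible_for_enrollment: bool

    def __post_init__(self) -> None:
        if not 0 <= self.score <= MAX_SCORE:
            raise ValueError("score out of range")


def _categorize(score: int, score6_category: RiskCategory) -> RiskCategory:
    if score <= 2:
        return RiskCategory.low
    if score <= 5:
        return RiskCategory.moderate
    if score == 6:
        return score6_category
    return RiskCategory.high


def compute_risk_score(
    symptoms: SymptomProfile,
    score6_category: RiskCategory = RiskCategory.high,
) -> RiskAssessment:
    """Score a symptom profile and derive risk category and eligibility.

    The pregnancy gate on the hypertension item is enforced by the
    :class:`~akicohort.types.SymptomProfile` validator, so every profile
    reaching this function scores at most one point for it and only when
    pregnant.
    """
    score = sum(symptoms.flags())
    category = _categorize(score, score6_category)
    return RiskAssessment(
        score=score,
        category=category,
        eligible_for_enrollment=score >= ELIGIBILITY_THRESHOLD,
    )
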