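"""Renal function primitives: CKD-EPI eGFR, unit conversion, proteinuria.

The 2009 CKD-EPI creatinine equation is used for adults:

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [female] * 1.159 [Black, when the race coefficient is enabled]

with Scr in mg/dl, k = 0.7 (female) / 0.9 (male) and a = -0.329 / -0.411.
The race coefficient is OFF by default, matching current practice; a switch
preserves the original published form.  Children (<18 y) are outside the
equation's validity; an optional bedside Schwartz fallback (requires height)
is provided but never applied implicitly.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

from scipy.optimize import brentq

from .types import DipstickResult, ProteinGrade, Sex

#: μmol/l per mg/dl of creatinine.
UMOL_PER_MGDL = 88.42

_KAPPA = {Sex.female: 0.7, Sex.male: 0.9}
_ALPHA = {Sex.female: -0.329, Sex.male: -0.411}


class EgfrEquation(str, enum.Enum):
    ckd_epi_2009 = "ckd_epi_2009"
    pediatric_fallback = "pediatric_fallback"


@dataclass(frozen=True)
class EgfrResult:
    """An eGFR value (ml/min/1.73 m²) with the threshold flags used downstream."""

    value: float
    equation_used: EgfrEquation
    below_60: bool
    below_15: bool

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("eGFR must be positive")
        if self.below_60 != (self.value < 60.0) or self.below_15 != (self.value < 15.0):
            raise ValueError("threshold flags inconsistent with value")

    @classmethod
    def of(cls, value: float, equation: EgfrEquation) -> "EgfrResult":
        return cls(value, equation, value < 60.0, value < 15.0)


def umol_to_mgdl(x: float) -> float:
    """Convert serum creatinine from μmol/l to mg/dl."""
    if x <= 0:
        raise ValueError("creatinine must be positive")
    return x / UMOL_PER_MGDL


def mgdl_to_umol(x: float) -> float:
    """Convert serum creatinine from mg/dl to μmol/l."""
    if x <= 0:
        raise ValueError("creatinine must be positive")
    return x * UMOL_PER_MGDL


def egfr_ckd_epi(
    scr_umol_l: float,
    age_years: float,
    sex: Sex,
    race_black: bool = False,
    race_coefficient: bool = False,
) -> EgfrResult:
    """2009 CKD-EPI creatinine eGFR for adults (age >= 18 years).

    ``race_black`` only has an effect when ``race_coefficient`` is enabled.
    """
    if scr_umol_l <= 0:
        raise ValueError("creatinine must be positive")
    if age_years < 18:
        raise ValueError("CKD-EPI is an adult equation; age must be >= 18")
    scr = umol_to_mgdl(scr_umol_l)
    kappa = _KAPPA[sex]
    alpha = _ALPHA[sex]
    ratio = scr / kappa
    value = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209
    value *= 0.993**age_years
    if sex is Sex.female:
        value *= 1.018
    if race_coefficient and race_black:
        value *= 1.159
    return EgfrResult.of(value, EgfrEquation.ckd_epi_2009)


def egfr_schwartz(scr_umol_l: float, height_cm: float) -> EgfrResult:
    """Bedside Schwartz eGFR for children: 36.5 * height[cm] / Scr[μmol/l]."""
    if scr_umol_l <= 0:
        raise ValueError("creatinine must be positive")
    if height_cm <= 0:
        raise ValueError("height must be positive")
    value = 36.5 * height_cm / scr_umol_l
    return EgfrResult.of(value, EgfrEquation.pediatric_fallback)


def scr_for_egfr(
    target_egfr: float,
    age_years: float,
    sex: Sex,
    race_black: bool = False,
    race_coefficient: bool = False,
) -> float:
    """Creatinine (μmol/l) at which CKD-EPI yields ``target_egfr`` — the
    numerical inverse of :func:`egfr_ckd_epi` in its strictly decreasing arm.
    Used by the cohort simulator to hit eGFR targets."""
    if target_egfr <= 0:
        raise ValueError("target eGFR must be positive")

    def f(scr: float) -> float:
        return (
            egfr_ckd_epi(scr, age_years, sex, race_black, race_coefficient).value
            - target_egfr
        )

    lo, hi = 1.0, 4000.0
    if f(lo) < 0:  # target above the equation's range at this age/sex
        raise ValueError("target eGFR unattainable for these covariates")
    return brentq(f, lo, hi, xtol=1e-9)


def is_proteinuric(dipstick: DipstickResult) -> bool:
    """Proteinuria positivity: dipstick protein >= 1+ (trace is negative)."""
    return dipstick.protein_grade >= ProteinGrade.plus1
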