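"""Kidney-status state machine over the 6-month follow-up schedule.

The per-patient computation proceeds in five steps:

1. enrollment status — CKD (known history, or a prior baseline creatinine
   within 12 months giving eGFR < 60), else AKD (enrollment eGFR < 60 or
   dipstick proteinuria >= 1+), else NKD;
2. AKI detection within 7 days — rise of >= 26.5 μmol/l within 48 h, rise to
   > 1.5x the reference creatinine within 7 days, or the mirror-image decline
   criteria, staged 1–3 through the KDIGO creatinine bands;
3. 7-day status — AKI (annotated with the originating enrollment group)
   supersedes the enrollment label, which is otherwise carried forward;
4. recovery at 1 month — complete / partial / none relative to the reference
   and peak creatinine, with dialysis dependence or eGFR < 15 forcing "none";
5. 3/6-month follow-up — new-onset CKD (non-CKD strata, visit eGFR < 60),
   CKD progression (CKD stratum, visit eGFR below the enrollment eGFR), and
   acute kidney disease appearing in patients still NKD at 7 days.

eGFR-based rules are applied to adults only; children are classified by
history, dipstick, and creatinine-change criteria (the adult CKD-EPI
equation does not apply, and no pediatric threshold is invented).  A patient
contributes to a timepoint's denominator only when the required sample
exists in that visit window.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, DeclineStaging, RunConfig, VisitWindows
from .renal import egfr_ckd_epi, is_proteinuric
from .types import (
    Cohort,
    CreatinineSample,
    PatientRecord,
    ProteinGrade,
    Sex,
    Visit,
)

#: Absolute creatinine change threshold, μmol/l (KDIGO 0.3 mg/dl).
ABS_DELTA_UMOL = 26.5
#: Ratio threshold for the 7-day criteria.
RATIO_THRESHOLD = 1.5
#: Stage-3 absolute creatinine threshold, μmol/l (KDIGO 4.0 mg/dl).
STAGE3_SCR_UMOL = 353.6
#: Pairwise window for the absolute-change criteria, hours.
PAIR_WINDOW_H = 48.0


class KidneyStatus(str, enum.Enum):
    NKD = "NKD"
    AKD = "AKD"
    CKD = "CKD"


class StatusLabel7d(str, enum.Enum):
    NKD = "NKD"
    AKD = "AKD"
    CKD = "CKD"
    AKI = "AKI"


class AKICriterion(str, enum.Enum):
    rise_48h_abs = "rise_48h_abs"
    rise_7d_ratio = "rise_7d_ratio"
    fall_48h_abs = "fall_48h_abs"
    fall_7d_ratio = "fall_7d_ratio"

    @property
    def is_decline(self) -> bool:
        return self in (AKICriterion.fall_48h_abs, AKICriterion.fall_7d_ratio)


class RecoveryStatus(str, enum.Enum):
    complete = "complete"
    partial = "partial"
    none = "none"
    not_assessable = "not_assessable"


class TriState(str, enum.Enum):
    yes = "yes"
    no = "no"
    not_assessable = "not_assessable"


@dataclass(frozen=True)
class AKIEvent:
    """A detected 7-day AKI with its triggering criterion and KDIGO stage."""

    detected: bool
    criterion: AKICriterion
    reference_scr: float
    extreme_scr: float
    stage: int
    severe: bool

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        if self.severe != (self.stage in (2, 3)):
            raise ValueError("severe flag inconsistent with stage")
        if not self.criterion.is_decline and self.extreme_scr < self.reference_scr:
            raise ValueError("rise criteria require extreme >= reference")


@dataclass
class KidneyStatusTimeline:
    """Per-patient classification at enrollment / 7 d / 1 / 3 / 6 months."""

    patient_id: str
    status_enrollment: Optional[KidneyStatus]
    aki_7d: Optional[AKIEvent]
    status_7d: Optional[StatusLabel7d]
    origin_group: Optional[KidneyStatus]  # enrollment group an AKI arose from
    recovery_1mo: RecoveryStatus
    akd_on_nkd: TriState
    new_onset_ckd_3mo: TriState
    new_onset_ckd_6mo: TriState
    ckd_progression_3mo: TriState
    ckd_progression_6mo: TriState


def assign_visit(time_h: float, windows: VisitWindows) -> Visit:
    """Assign a sample time to the nearest containing visit window."""
    if time_h < 0:
        return Visit.prior_baseline
    if time_h == 0:
        return Visit.enrollment
    best: tuple[float, Visit] | None = None
    for name in ("h48", "day7", "month1", "month3", "month6"):
        w = getattr(windows, name)
        if w.lo <= time_h <= w.hi:
            dist = abs(time_h - w.nominal)
            if best is None or dist < best[0]:
                best = (dist, Visit(name))
    return best[1] if best else Visit.other


def resolve_visits(
    samples: Sequence[CreatinineSample], windows: VisitWindows
) -> list[CreatinineSample]:
    """Fill in ``other`` visit labels from the window assignment rule."""
    out = []
    for s in samples:
        if s.visit is Visit.other:
            v = assign_visit(s.time, windows)
            out.append(s.model_copy(update={"visit": v}) if v is not s.visit else s)
        else:
            out.append(s)
    return out


def _egfr_value(
    scr: float, record: PatientRecord, config: RunConfig
) -> Optional[float]:
    """Adult CKD-EPI eGFR, or None when the equation does not apply."""
    if not record.is_adult:
        return None
    race_black = (record.ethnicity or "").lower() == "african"
    return egfr_ckd_epi(
        scr,
        record.age_years,
        record.sex,
        race_black=race_black,
        race_coefficient=config.egfr.race_coefficient,
    ).value


def classify_enrollment(
    record: PatientRecord, config: RunConfig = DEFAULT_CONFIG
) -> Optional[KidneyStatus]:
    """Enrollment status with precedence CKD > AKD > NKD.

    Returns None (not classifiable) when the enrollment creatinine is
    missing; cohort runs carry the gap forward instead of halting.
    """
    enroll = record.enrollment_sample()
    if enroll is None:
        return None
    if record.known_ckd_history:
        return KidneyStatus.CKD
    prior = record.prior_baseline_sample()
    if prior is not None:
        egfr = _egfr_value(prior.value, record, config)
        if egfr is not None and egfr < 60.0:
            return KidneyStatus.CKD
    egfr = _egfr_value(enroll.value, record, config)
    if egfr is not None and egfr < 60.0:
        return KidneyStatus.AKD
    dip = record.enrollment_dipstick()
    if dip is not None and is_proteinuric(dip):
        return KidneyStatus.AKD
    return KidneyStatus.NKD


def reference_creatinine(
    record: PatientRecord, status: Optional[KidneyStatus]
) -> Optional[float]:
    """Reference creatinine for the rise criteria.

    The enrollment value for patients without a prior baseline; the prior
    baseline for CKD patients who have one.  Decline criteria always compare
    against the enrollment value.
    """
    enroll = record.enrollment_sample()
    if enroll is None:
        return None
    if status is KidneyStatus.CKD:
        prior = record.prior_baseline_sample()
        if prior is not None:
            return prior.value
    return enroll.value


def detect_aki(
    samples: Sequence[CreatinineSample],
    reference_scr: float,
    dialyzed_within_7d: bool = False,
    config: RunConfig = DEFAULT_CONFIG,
) -> Optional[AKIEvent]:
    """Scan creatinine samples in the 7-day window for the four AKI criteria.

    ``samples`` must contain the enrollment sample (time 0); only samples up
    to the end of the day-7 visit window participate.  The recorded criterion
    is the first satisfied in the order: 48 h absolute rise, 7-day ratio
    rise, 48 h absolute fall, 7-day ratio fall.
    """
    window_end = config.visit_windows.day7.hi
    window = sorted(
        (s for s in samples if 0.0 <= s.time <= window_end), key=lambda s: s.time
    )
    if not window:
        return None
    enroll = next((s for s in window if s.time == 0.0), None)
    if enroll is None:
        return None

    rise_abs = fall_abs = False
    for i, si in enumerate(window):
        for sj in window[i + 1 :]:
            if sj.time - si.time > PAIR_WINDOW_H:
                break
            delta = sj.value - si.value
            if delta >= ABS_DELTA_UMOL:
                rise_abs = True
            if -delta >= ABS_DELTA_UMOL:
                fall_abs = True
    rise_ratio = any(s.value > RATIO_THRESHOLD * reference_scr for s in window)
    later = [s for s in window if s.time > 0.0]
    fall_ratio = any(enroll.value > RATIO_THRESHOLD * s.value for s in later)

    criterion: Optional[AKICriterion] = None
    for crit, hit in (
        (AKICriterion.rise_48h_abs, rise_abs),
        (AKICriterion.rise_7d_ratio, rise_ratio),
        (AKICriterion.fall_48h_abs, fall_abs),
        (AKICriterion.fall_7d_ratio, fall_ratio),
    ):
        if hit:
            criterion = crit
            break
    if criterion is None:
        return None

    peak = max(s.value for s in window)
    nadir = min((s.value for s in later), default=enroll.value)
    any_rise = rise_abs or rise_ratio
    any_fall = fall_abs or fall_ratio

    # A 48 h absolute rise can occur while the whole episode sits below a
    # chronic prior-baseline reference; the episode reference then falls back
    # to the enrollment value (peak >= enrollment always holds).
    rise_reference = reference_scr if peak >= reference_scr else enroll.value

    r = 0.0
    if any_rise:
        r = max(r, peak / rise_reference)
    if any_fall:
        if config.decline_staging is DeclineStaging.ratio_bands:
            r = max(r, enroll.value / nadir)
        # always_stage1: decline contributes no ratio, landing in stage 1
    stage = 1
    if 2.0 < r <= 3.0:
        stage = 2
    elif r > 3.0:
        stage = 3
    if (any_rise and peak >= STAGE3_SCR_UMOL) or dialyzed_within_7d:
        stage = 3

    extreme = peak if not criterion.is_decline else enroll.value
    reference = rise_reference if not criterion.is_decline else enroll.value
    return AKIEvent(
        detected=True,
        criterion=criterion,
        reference_scr=reference,
        extreme_scr=extreme,
        stage=stage,
        severe=stage in (2, 3),
    )


def status_at_7d(
    enrollment_status: Optional[KidneyStatus], event: Optional[AKIEvent]
) -> Optional[StatusLabel7d]:
    """AKI supersedes the enrollment label; non-AKI patients keep their group."""
    if enrollment_status is None:
        return None
    if event is not None and event.detected:
        return StatusLabel7d.AKI
    return StatusLabel7d(enrollment_status.value)


def classify_recovery(
    event: AKIEvent,
    scr_1mo: Optional[float],
    dialysis_dependent_1mo: bool,
    record: PatientRecord,
    config: RunConfig = DEFAULT_CONFIG,
) -> RecoveryStatus:
    """Recovery class at 1 month for a detected AKI.

    "None" when dialysis-dependent or the 1-month creatinine corresponds to
    eGFR < 15 (adults); otherwise complete (<= reference), partial (between
    reference and peak) or none (>= peak).  Missing 1-month creatinine makes
    recovery not assessable.
    """
    if scr_1mo is None:
        return RecoveryStatus.not_assessable
    if dialysis_dependent_1mo:
        return RecoveryStatus.none
    egfr = _egfr_value(scr_1mo, record, config)
    if egfr is not None and egfr < 15.0:
        return RecoveryStatus.none
    if scr_1mo <= event.reference_scr:
        return RecoveryStatus.complete
    if scr_1mo < event.extreme_scr:
        return RecoveryStatus.partial
    return RecoveryStatus.none


def _sample_at(
    samples: Sequence[CreatinineSample], visit: Visit
) -> Optional[CreatinineSample]:
    hits = [s for s in samples if s.visit is visit]
    return hits[0] if hits else None


def build_timeline(
    record: PatientRecord, config: RunConfig = DEFAULT_CONFIG
) -> KidneyStatusTimeline:
    """Run the full state machine for one patient."""
    samples = resolve_visits(record.creatinine_series, config.visit_windows)
    status0 = classify_enrollment(record, config)

    event: Optional[AKIEvent] = None
    if status0 is not None:
        ref = reference_creatinine(record, status0)
        assert ref is not None
        event = detect_aki(samples, ref, record.dialyzed, config)
    label7 = status_at_7d(status0, event)
    origin = status0 if (event is not None and status0 is not None) else None

    m1 = _sample_at(samples, Visit.month1)
    recovery = RecoveryStatus.not_assessable
    if event is not None:
        recovery = classify_recovery(
            event, m1.value if m1 else None, False, record, config
        )

    akd_on_nkd = TriState.not_assessable
    if label7 is StatusLabel7d.NKD:
        dip1 = record.dipstick_at(Visit.month1)
        egfr1 = _egfr_value(m1.value, record, config) if m1 else None
        if egfr1 is None and dip1 is None:
            akd_on_nkd = TriState.not_assessable
        elif (egfr1 is not None and egfr1 < 60.0) or (
            dip1 is not None and is_proteinuric(dip1)
        ):
            akd_on_nkd = TriState.yes
        else:
            akd_on_nkd = TriState.no

    new3 = new6 = prog3 = prog6 = TriState.not_assessable
    enroll = record.enrollment_sample()
    for visit, is_3mo in ((Visit.month3, True), (Visit.month6, False)):
        s = _sample_at(samples, visit)
        if s is None or status0 is None:
            continue
        egfr = _egfr_value(s.value, record, config)
        if egfr is None:
            continue  # pediatric: eGFR thresholds not applied
        if status0 is KidneyStatus.CKD:
            egfr0 = _egfr_value(enroll.value, record, config) if enroll else None
            if egfr0 is None:
                continue
            verdict = TriState.yes if egfr < egfr0 else TriState.no
            if is_3mo:
                prog3 = verdict
            else:
                prog6 = verdict
        else:
            verdict = TriState.yes if egfr < 60.0 else TriState.no
            if is_3mo:
                new3 = verdict
            else:
                new6 = verdict

    return KidneyStatusTimeline(
        patient_id=record.patient_id,
        status_enrollment=status0,
        aki_7d=event,
        status_7d=label7,
        origin_group=origin,
        recovery_1mo=recovery,
        akd_on_nkd=akd_on_nkd,
        new_onset_ckd_3mo=new3,
        new_onset_ckd_6mo=new6,
        ckd_progression_3mo=prog3,
        ckd_progression_6mo=prog6,
    )


def classify_cohort(
    cohort: Cohort, config: RunConfig = DEFAULT_CONFIG
) -> list[KidneyStatusTimeline]:
    return [build_timeline(r, config) for r in cohort]


def timelines_to_frame(timelines: Sequence[KidneyStatusTimeline]) -> pd.DataFrame:
    """Flatten timelines to one row per patient (the ``timeline.csv`` schema)."""
    rows = []
    for t in timelines:
        ev = t.aki_7d
        rows.append(
            {
                "patient_id": t.patient_id,
                "status_enrollment": t.status_enrollment.value
                if t.status_enrollment
                else "",
                "status_7d": t.status_7d.value if t.status_7d else "",
                "origin_group": t.origin_group.value if t.origin_group else "",
                "aki_detected": bool(ev),
                "aki_criterion": ev.criterion.value if ev else "",
                "aki_stage": ev.stage if ev else math.nan,
                "aki_severe": ev.severe if ev else False,
                "reference_scr": ev.reference_scr if ev else math.nan,
                "extreme_scr": ev.extreme_scr if ev else math.nan,
                "recovery_1mo": t.recovery_1mo.value,
                "akd_on_nkd": t.akd_on_nkd.value,
                "new_onset_ckd_3mo": t.new_onset_ckd_3mo.value,
                "new_onset_ckd_6mo": t.new_onset_ckd_6mo.value,
                "ckd_progression_3mo": t.ckd_progression_3mo.value,
                "ckd_progression_6mo": t.ckd_progression_6mo.value,
            }
        )
    return pd.DataFrame(rows)
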