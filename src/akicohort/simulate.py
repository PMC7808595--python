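"""Synthetic community-AKI cohort generator.

The generator reproduces the statistical structure the analysis pipeline
assumes — a two-phase enrolled cohort with a CKD/AKD/NKD mixture at
presentation, status-conditional 7-day AKI risk split between creatinine-rise
and creatinine-decline presentations, KDIGO stage mixture, phase-dependent
loss to lab follow-up, and status-dependent mortality — without any
mechanistic creatinine-kinetics model.  Within-patient trajectories are
phenomenological templates (stable, rising-to-plateau, resolving-decline)
whose amplitudes are drawn to guarantee or avoid the classification
thresholds the assigned label requires.

Ground truth is defined as the label set produced by the classifier on the
noiseless, dropout-free (but death-censored) trajectory: death is a real
event, whereas measurement noise and loss to follow-up are observation
corruptions.  With measurement CV 0 and no dropout the observed cohort
coincides with that trajectory, so pipeline labels equal ground truth
exactly; under noise, recovery of the configured proportions degrades
gracefully and is checked statistically.

All randomness flows from a single seed through two child streams (latent
cohort construction; measurement noise), so trajectories are reproducible
and the noise level can be varied with common random numbers.
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import DEFAULT_CONFIG, RunConfig
from .renal import scr_for_egfr
from .status import (
    KidneyStatus,
    StatusLabel7d,
    classify_cohort,
    timelines_to_frame,
)
from .types import (
    Cohort,
    CreatinineSample,
    DipstickResult,
    Disposition,
    PatientRecord,
    Phase,
    ProteinGrade,
    Sex,
    SymptomProfile,
    SYMPTOM_FIELDS,
    Visit,
)

#: Nominal visit times, hours since enrollment.
VISIT_TIMES_H = {
    Visit.enrollment: 0.0,
    Visit.h48: 48.0,
    Visit.day7: 168.0,
    Visit.month1: 720.0,
    Visit.month3: 2160.0,
    Visit.month6: 4320.0,
}

_MIX_TOL = 1e-9


def _check_mixture(values, name: str) -> None:
    if any(not (0.0 <= v <= 1.0) for v in values):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(values) - 1.0) > _MIX_TOL:
        raise ValueError(f"{name}: mixture must sum to 1 (got {sum(values)!r})")


class SimulationConfig(BaseModel):
    """Cohort-level parameters; defaults reproduce the study-scale marginals."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_total: int = Field(default=2101, ge=1)
    phase_split: float = Field(default=978 / 2101, ge=0.0, le=1.0)

    # enrollment status mixture (CKD, AKD, NKD)
    p_ckd: float = 0.094
    p_akd: float = 0.570
    p_nkd: float = 0.336

    # conditional 7-day AKI probability per enrollment status
    aki_prob_ckd: float = 0.47
    aki_prob_akd: float = 0.37
    aki_prob_nkd: float = 0.14
    #: fraction of AKI presenting as a creatinine decline (resolving episode)
    decline_fraction: float = 0.415
    #: KDIGO stage mixture among AKI (stages 1, 2, 3)
    stage_mixture: tuple[float, float, float] = (0.401, 0.220, 0.379)
    #: 1-month recovery mixture among rise-detected AKI (complete, partial, none)
    recovery_mixture: tuple[float, float, float] = (0.60, 0.20, 0.20)

    # AKD composition at enrollment (reduced eGFR alone / both / proteinuria alone)
    akd_scr_alone: float = 0.658
    akd_scr_and_proteinuria: float = 0.182
    akd_proteinuria_alone: float = 0.160
    ckd_proteinuria_fraction: float = 0.335
    ckd_known_history_fraction: float = 0.7

    # longitudinal persistence probabilities
    p_new_ckd_after_aki: float = 0.184
    p_persistent_ckd_akd: float = 0.341
    p_ckd_progression: float = 0.545
    p_akd_on_nkd: float = 0.041

    # demographics
    child_fraction: float = 0.13
    female_fraction: float = 0.532
    adult_age_log_median: float = math.log(47.0)
    adult_age_log_sigma: float = 0.49
    pregnancy_fraction: float = 0.10

    #: per-symptom marginal prevalence (enrollment requires risk score >= 3,
    #: emulated by redrawing low-scoring profiles; redraws are tallied as
    #: screened-but-excluded low-risk patients)
    symptom_prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "decreased_urine_output": 0.40,
            "hypotension_shock": 0.18,
            "coma": 0.05,
            "jaundice": 0.12,
            "anemia": 0.35,
            "confusion": 0.15,
            "dyspnea": 0.35,
            "respiratory_infection": 0.40,
            "petechiae": 0.05,
            "ecchymosis": 0.05,
            "bleeding": 0.10,
            "hypertension_in_pregnancy": 0.15,
        }
    )
    symptom_status_multiplier: dict[str, float] = Field(
        default_factory=lambda: {"NKD": 0.9, "AKD": 1.05, "CKD": 1.1}
    )

    # care process
    admission_prob_by_7d_status: dict[str, float] = Field(
        default_factory=lambda: {"AKI": 0.82, "AKD": 0.46, "NKD": 0.34, "CKD": 0.46}
    )
    admission_phase_multiplier: dict[str, float] = Field(
        default_factory=lambda: {"observation": 1.10, "intervention": 0.91}
    )
    fluids_prob: dict[str, float] = Field(
        default_factory=lambda: {"observation": 0.730, "intervention": 0.778}
    )
    iv_given_fluids: float = 0.92
    oral_given_fluids: float = 0.51
    diuretics_prob: float = 0.09
    dialysis_indicated_stage3: float = 0.35
    dialyzed_given_indicated: float = 0.55

    # observation process
    measurement_cv: float = Field(default=0.07, ge=0.0)
    dropout_1mo: dict[str, float] = Field(
        default_factory=lambda: {"observation": 0.27, "intervention": 0.18}
    )
    late_dropout: float = 0.45
    #: multiplies the dropout probability for patients with kidney dysfunction
    #: at 7 days, to probe informative-dropout bias (1.0 = independent dropout)
    informative_dropout_multiplier: float = 1.0

    mortality_by_7d_status: dict[str, float] = Field(
        default_factory=lambda: {"CKD": 0.226, "AKD": 0.168, "AKI": 0.135, "NKD": 0.059}
    )

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        _check_mixture((self.p_ckd, self.p_akd, self.p_nkd), "status mixture")
        _check_mixture(self.stage_mixture, "stage mixture")
        _check_mixture(self.recovery_mixture, "recovery mixture")
        _check_mixture(
            (self.akd_scr_alone, self.akd_scr_and_proteinuria, self.akd_proteinuria_alone),
            "AKD subtype mixture",
        )
        for name in (
            "aki_prob_ckd", "aki_prob_akd", "aki_prob_nkd", "decline_fraction",
            "child_fraction", "female_fraction", "late_dropout",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for d in (self.dropout_1mo, self.mortality_by_7d_status, self.fluids_prob):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("probabilities must lie in [0, 1]")
        return self


class SimulatedCohort(BaseModel):
    """A generated cohort plus its retained ground-truth label table."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    cohort: Cohort
    truth: pd.DataFrame


# ---------------------------------------------------------------------------


def _draw_symptoms(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    status: KidneyStatus,
    pregnant: bool,
) -> tuple[SymptomProfile, int]:
    """Rejection-sample a profile with risk score >= 3; count rejected draws."""
    mult = cfg.symptom_status_multiplier.get(status.value, 1.0)
    rejected = 0
    while True:
        flags = {}
        for name in SYMPTOM_FIELDS:
            p = min(0.95, cfg.symptom_prevalence.get(name, 0.0) * mult)
            if name == "hypertension_in_pregnancy" and not pregnant:
                flags[name] = False
            else:
                flags[name] = bool(rng.random() < p)
        if sum(flags.values()) >= 3:
            return SymptomProfile(is_pregnant=pregnant, **flags), rejected
        rejected += 1


def _scr_normal(rng: np.random.Generator, age: float, sex: Sex) -> float:
    """A plausible normal creatinine, μmol/l."""
    if age < 18:
        return float(rng.uniform(25.0, 60.0))
    return scr_for_egfr(float(rng.uniform(70.0, 110.0)), age, sex)


def _scr_for_target(
    rng: np.random.Generator, age: float, sex: Sex, lo: float, hi: float
) -> float:
    """Creatinine hitting a uniform eGFR target in [lo, hi] (adults)."""
    return scr_for_egfr(float(rng.uniform(lo, hi)), age, sex)


#: Ceiling for stable elevated baselines, μmol/l.  Keeps a stable patient's
#: 48 h pair comfortably clear of the 26.5 μmol/l change criterion at the
#: default 7% measurement CV, and keeps stage-2 rise peaks below the 353.6
#: μmol/l absolute stage-3 threshold (2.7 x 145 < 392, capped further below).
_ELEVATED_SCR_CAP = 145.0
#: Stage-2 peaks stay below this so the absolute stage-3 rule never fires.
_STAGE2_PEAK_CAP = 335.0


def _scr_elevated(rng: np.random.Generator, age: float, sex: Sex) -> float:
    """A stable reduced-eGFR baseline (target eGFR 40-54), capped so the
    trajectory templates avoid the change thresholds they must not trip."""
    return min(_scr_for_target(rng, age, sex, 40.0, 54.0), _ELEVATED_SCR_CAP)


class _Latent:
    """Scratch holder for one patient's latent attributes."""

    __slots__ = (
        "pid", "age", "sex", "phase", "status", "aki", "decline", "stage",
        "recovery", "proteinuric", "c_enroll", "c_baseline", "c_low_egfr",
        "values", "admitted", "death_time", "dropout_time", "dialyzed",
        "dialysis_indicated", "m1_proteinuria",
    )


def _build_trajectory(
    rng: np.random.Generator, cfg: SimulationConfig, lat: "_Latent"
) -> dict[Visit, float]:
    """Latent creatinine at every scheduled visit, honoring the assigned label."""
    c0 = lat.c_enroll
    values: dict[Visit, float] = {Visit.enrollment: c0}

    if not lat.aki:
        for v in (Visit.h48, Visit.day7, Visit.month1):
            values[v] = c0
        # follow-up course by stratum
        if lat.status is KidneyStatus.CKD:
            factor = (
                rng.uniform(1.15, 1.35)
                if rng.random() < cfg.p_ckd_progression
                else rng.uniform(0.82, 0.95)
            )
            values[Visit.month3] = values[Visit.month6] = c0 * factor
        elif lat.status is KidneyStatus.AKD and lat.c_low_egfr:
            if rng.random() < cfg.p_persistent_ckd_akd:
                values[Visit.month3] = values[Visit.month6] = c0
            else:
                resolved = (
                    _scr_for_target(rng, lat.age, lat.sex, 65.0, 95.0)
                    if lat.age >= 18
                    else c0 * 0.7
                )
                values[Visit.month1] = values[Visit.month3] = resolved
                values[Visit.month6] = resolved
        else:  # NKD or proteinuria-only AKD: stable normal
            akd_on_nkd = (
                lat.status is KidneyStatus.NKD
                and rng.random() < cfg.p_akd_on_nkd
            )
            lat.m1_proteinuria = False
            if akd_on_nkd:
                if lat.age >= 18:
                    values[Visit.month1] = _scr_for_target(
                        rng, lat.age, lat.sex, 40.0, 55.0
                    )
                else:
                    lat.m1_proteinuria = True
            values.setdefault(Visit.month1, c0)
            values[Visit.month3] = values[Visit.month6] = values[Visit.month1]
        return values

    # --- AKI templates -----------------------------------------------------
    ref = lat.c_baseline  # rise reference (prior baseline for CKD, else c0)
    stage = lat.stage
    if not lat.decline:
        if stage == 1:
            if lat.admitted and c0 >= 80.0:
                peak = c0 + float(rng.uniform(45.0, 65.0))
                peak = min(peak, 1.9 * ref) if peak > 1.9 * ref else peak
            else:
                peak = ref * float(rng.uniform(1.70, 1.88))
        elif stage == 2:
            hi = min(2.70, _STAGE2_PEAK_CAP / ref) if ref > 0 else 2.70
            peak = ref * float(rng.uniform(2.25, max(2.30, hi)))
        else:
            peak = ref * float(rng.uniform(3.40, 4.80))
        peak = max(peak, c0 + 1.0)
        values[Visit.h48] = peak
        values[Visit.day7] = peak
        extreme = peak
        # 1-month recovery (relative to the rise reference)
        comp, part, _none = cfg.recovery_mixture
        u = rng.random()
        if u < comp:
            lat.recovery = "complete"
            values[Visit.month1] = ref * float(rng.uniform(0.80, 0.98))
        elif u < comp + part:
            lat.recovery = "partial"
            frac = float(rng.uniform(0.15, 0.85))
            values[Visit.month1] = ref + frac * (extreme - ref)
        else:
            lat.recovery = "none"
            values[Visit.month1] = extreme * float(rng.uniform(1.02, 1.15))
    else:
        rho = {1: rng.uniform(1.70, 1.88), 2: rng.uniform(2.30, 2.70),
               3: rng.uniform(3.40, 4.80)}[stage]
        nadir = c0 / float(rho)
        values[Visit.h48] = math.sqrt(c0 * nadir)
        values[Visit.day7] = nadir
        lat.recovery = "complete"  # resolving episode keeps falling
        values[Visit.month1] = nadir * float(rng.uniform(0.90, 1.00))

    # 3/6-month course after AKI
    if rng.random() < cfg.p_new_ckd_after_aki and lat.age >= 18:
        late = _scr_for_target(rng, lat.age, lat.sex, 35.0, 55.0)
    else:
        late = (
            _scr_for_target(rng, lat.age, lat.sex, 70.0, 100.0)
            if lat.age >= 18
            else _scr_normal(rng, lat.age, lat.sex)
        )
    values[Visit.month3] = values[Visit.month6] = late
    return values


def generate_cohort(
    config: SimulationConfig, run_config: RunConfig = DEFAULT_CONFIG
) -> SimulatedCohort:
    """Draw a cohort; deterministic given ``config.seed``.

    Returns the observed cohort (noise + censoring applied) together with the
    ground-truth label table derived from the noiseless trajectories.
    """
    seed_latent, seed_noise = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(seed_latent)
    noise_rng = np.random.default_rng(seed_noise)

    statuses = (KidneyStatus.CKD, KidneyStatus.AKD, KidneyStatus.NKD)
    status_p = (config.p_ckd, config.p_akd, config.p_nkd)
    aki_p = {
        KidneyStatus.CKD: config.aki_prob_ckd,
        KidneyStatus.AKD: config.aki_prob_akd,
        KidneyStatus.NKD: config.aki_prob_nkd,
    }

    truth_records: list[PatientRecord] = []
    latents: list[_Latent] = []
    screened_out = {Phase.observation: 0, Phase.intervention: 0}

    for i in range(config.n_total):
        lat = _Latent()
        lat.pid = f"P{i:05d}"
        lat.phase = (
            Phase.observation
            if rng.random() < config.phase_split
            else Phase.intervention
        )
        child = rng.random() < config.child_fraction
        if child:
            lat.age = float(rng.uniform(0.2, 17.9))
        else:
            lat.age = float(
                np.clip(
                    rng.lognormal(config.adult_age_log_median, config.adult_age_log_sigma),
                    18.0,
                    96.0,
                )
            )
        lat.sex = Sex.female if rng.random() < config.female_fraction else Sex.male
        lat.status = statuses[int(rng.choice(3, p=status_p))]
        lat.aki = rng.random() < aki_p[lat.status]
        lat.decline = lat.aki and (rng.random() < config.decline_fraction)
        lat.stage = (
            1 + int(rng.choice(3, p=config.stage_mixture)) if lat.aki else 0
        )
        lat.recovery = ""
        lat.m1_proteinuria = False

        known_history = False
        prior_baseline: Optional[float] = None
        proteinuric = False
        lat.c_low_egfr = False

        adult = lat.age >= 18.0
        if lat.status is KidneyStatus.CKD:
            if adult and rng.random() >= config.ckd_known_history_fraction:
                prior_baseline = _scr_elevated(rng, lat.age, lat.sex)
            else:
                known_history = True
            proteinuric = rng.random() < config.ckd_proteinuria_fraction
            base = (
                prior_baseline
                if prior_baseline is not None
                else (
                    _scr_elevated(rng, lat.age, lat.sex)
                    if adult
                    else float(rng.uniform(80.0, 140.0))
                )
            )
            if lat.aki and lat.decline:
                c0 = base * float(rng.uniform(1.15, 1.35))
            else:
                c0 = base
            lat.c_baseline = base
            lat.c_enroll = c0
        elif lat.status is KidneyStatus.AKD:
            u = rng.random()
            if not adult:
                subtype = "prot"  # children: structural criterion only
            elif lat.aki and lat.decline:
                # resolving episode presents with elevated creatinine
                subtype = "scr" if u < 0.8 else "both"
            elif u < config.akd_scr_alone:
                subtype = "scr"
            elif u < config.akd_scr_alone + config.akd_scr_and_proteinuria:
                subtype = "both"
            else:
                subtype = "prot"
            proteinuric = subtype in ("both", "prot")
            if subtype in ("scr", "both") and adult:
                lat.c_enroll = _scr_elevated(rng, lat.age, lat.sex)
                lat.c_low_egfr = True
            elif not adult and lat.aki and lat.decline:
                lat.c_enroll = float(rng.uniform(90.0, 140.0))
            else:
                lat.c_enroll = _scr_normal(rng, lat.age, lat.sex)
            lat.c_baseline = lat.c_enroll
        else:  # NKD
            if lat.aki and lat.decline:
                lat.c_enroll = (
                    _scr_for_target(rng, lat.age, lat.sex, 62.0, 75.0)
                    if adult
                    else float(rng.uniform(70.0, 110.0))
                )
            else:
                lat.c_enroll = _scr_normal(rng, lat.age, lat.sex)
            lat.c_baseline = lat.c_enroll
        lat.proteinuric = proteinuric

        label7 = StatusLabel7d.AKI if lat.aki else StatusLabel7d(lat.status.value)
        p_adm = config.admission_prob_by_7d_status[label7.value]
        p_adm = min(0.97, p_adm * config.admission_phase_multiplier[lat.phase.value])
        lat.admitted = rng.random() < p_adm

        lat.dialysis_indicated = False
        lat.dialyzed = False
        if lat.aki and lat.stage == 3:
            lat.dialysis_indicated = rng.random() < config.dialysis_indicated_stage3
            lat.dialyzed = (
                lat.dialysis_indicated
                and rng.random() < config.dialyzed_given_indicated
            )
        elif lat.status in (KidneyStatus.AKD, KidneyStatus.CKD) and not lat.aki:
            lat.dialysis_indicated = rng.random() < 0.02

        lat.values = _build_trajectory(rng, config, lat)

        # outcomes: death per 7-day status; lab dropout per phase
        p_death = config.mortality_by_7d_status[label7.value]
        lat.death_time = (
            float(rng.uniform(192.0, 4300.0)) if rng.random() < p_death else None
        )
        p_lost = config.dropout_1mo[lat.phase.value]
        if label7 is not StatusLabel7d.NKD:
            p_lost = min(1.0, p_lost * config.informative_dropout_multiplier)
        if rng.random() < p_lost:
            lat.dropout_time = float(rng.uniform(72.0, 718.0))
        elif rng.random() < config.late_dropout:
            lat.dropout_time = float(rng.uniform(730.0, 4310.0))
        else:
            lat.dropout_time = None

        pregnant = (
            lat.sex is Sex.female and 15.0 <= lat.age <= 45.0
            and rng.random() < config.pregnancy_fraction
        )
        symptoms, rejected = _draw_symptoms(rng, config, lat.status, pregnant)
        screened_out[lat.phase] += rejected

        fluids = rng.random() < config.fluids_prob[lat.phase.value]
        iv = fluids and rng.random() < config.iv_given_fluids
        oral = fluids and (
            (rng.random() < config.oral_given_fluids) if iv else True
        )
        diuretics = rng.random() < config.diuretics_prob

        if lat.admitted:
            hours = float(np.clip(rng.lognormal(math.log(96.0), 0.8), 25.0, 4000.0))
        else:
            med = 1.6 if lat.phase is Phase.observation else 4.0
            hours = float(np.clip(rng.lognormal(math.log(med), 1.0), 0.1, 23.9))

        # --- assemble the noiseless (truth) record -------------------------
        death_cut = lat.death_time if lat.death_time is not None else math.inf
        series = []
        if prior_baseline is not None:
            series.append(
                CreatinineSample(
                    value=prior_baseline,
                    time=float(-rng.uniform(720.0, 8000.0)),
                    visit=Visit.prior_baseline,
                )
            )
        for visit, t in VISIT_TIMES_H.items():
            if visit is Visit.h48 and not lat.admitted:
                continue
            if t > death_cut:
                continue
            series.append(
                CreatinineSample(value=lat.values[visit], time=t, visit=visit)
            )
        dips = []
        grade = (
            ProteinGrade(int(rng.choice([2, 3, 4], p=[0.5, 0.35, 0.15])))
            if proteinuric
            else ProteinGrade(int(rng.choice([0, 1], p=[0.85, 0.15])))
        )
        dips.append(DipstickResult(protein_grade=grade, visit=Visit.enrollment))
        if lat.status is KidneyStatus.NKD and death_cut > 720.0:
            m1_grade = ProteinGrade.plus1 if lat.m1_proteinuria else ProteinGrade.negative
            dips.append(
                DipstickResult(protein_grade=m1_grade, visit=Visit.month1, time=720.0)
            )

        last_contact = (
            lat.death_time
            if lat.death_time is not None
            else (lat.dropout_time if lat.dropout_time is not None else 4380.0)
        )
        truth_records.append(
            PatientRecord(
                patient_id=lat.pid,
                age_years=lat.age,
                sex=lat.sex,
                phase=lat.phase,
                symptoms=symptoms,
                known_ckd_history=known_history,
                creatinine_series=series,
                dipsticks=dips,
                disposition=(
                    Disposition.admitted if lat.admitted else Disposition.sent_home
                ),
                hours_in_facility=hours,
                dialysis_indicated=lat.dialysis_indicated,
                dialyzed=lat.dialyzed,
                received_oral_fluids=oral,
                received_iv_fluids=iv,
                received_diuretics=diuretics,
                death_time=lat.death_time,
                last_contact_time=last_contact,
            )
        )
        latents.append(lat)

    # --- ground truth: classify the noiseless, dropout-free records --------
    truth_cohort = Cohort(records=truth_records)
    truth_frame = timelines_to_frame(classify_cohort(truth_cohort, run_config))
    truth_frame["phase"] = [lat.phase.value for lat in latents]
    truth_frame["assigned_status"] = [lat.status.value for lat in latents]
    truth_frame["assigned_aki"] = [lat.aki for lat in latents]
    truth_frame["assigned_stage"] = [lat.stage for lat in latents]
    truth_frame["died"] = [lat.death_time is not None for lat in latents]
    truth_frame["lost_by_1mo"] = [
        lat.dropout_time is not None and lat.dropout_time < 720.0 for lat in latents
    ]

    # --- observation: multiplicative noise + dropout censoring -------------
    cv = config.measurement_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    observed_records = []
    for rec, lat in zip(truth_records, latents):
        cut = lat.dropout_time if lat.dropout_time is not None else math.inf
        series = []
        for s in rec.creatinine_series:
            z = noise_rng.standard_normal()  # drawn for every sample: common
            if s.time > cut:  # random numbers across CV settings
                continue
            factor = math.exp(sigma * z - 0.5 * sigma * sigma) if cv > 0 else 1.0
            series.append(s.model_copy(update={"value": s.value * factor}))
        dips = [d for d in rec.dipsticks if d.time <= cut]
        observed_records.append(
            rec.model_copy(update={"creatinine_series": series, "dipsticks": dips})
        )

    cohort = Cohort(
        records=observed_records,
        provenance={
            "generator": "akicohort.simulate",
            "seed": config.seed,
            "n_total": config.n_total,
            "screened_low_risk": {p.value: n for p, n in screened_out.items()},
            "config": config.model_dump(mode="json"),
        },
    )
    return SimulatedCohort(cohort=cohort, truth=truth_frame)


def ground_truth_confusion(
    truth: pd.DataFrame, observed_timeline: pd.DataFrame, field: str = "status_7d"
) -> pd.DataFrame:
    """Confusion matrix (truth rows x observed columns) for a timeline field."""
    merged = truth[["patient_id", field]].merge(
        observed_timeline[["patient_id", field]],
        on="patient_id",
        suffixes=("_truth", "_observed"),
    )
    return pd.crosstab(merged[f"{field}_truth"], merged[f"{field}_observed"])
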