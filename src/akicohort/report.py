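"""Presentation layer: flow accounting, phase comparisons, mortality tables.

Every percentage is recomputed from its numerator/denominator pair at render
time, and comparison rows are invariant to the order of patients in the
input files.  Rendering conventions: percentages to 1 decimal, p-values to
3 decimals (``<0.001`` below that), CI endpoints to 2 decimals.
"""
from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import pandas as pd
import yaml

from .config import DEFAULT_CONFIG, FisherConvention, RunConfig
from .status import KidneyStatusTimeline, StatusLabel7d
from .stats import ContingencyTable2x2, exact_or_test, holm_adjust
from .types import Cohort, PatientRecord, Phase

#: End of the 1-month window used for loss-to-follow-up accounting, hours.
MONTH1_H = 720.0
_TIMEPOINTS_H = {"7d": 168.0, "1mo": 720.0, "3mo": 2160.0, "6mo": 4320.0}


def fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def fmt_pct(num: int, den: int) -> str:
    return "-" if den == 0 else f"{100.0 * num / den:.1f}"


@dataclass(frozen=True)
class ComparisonSpec:
    """One named 2x2 phase comparison with explicit group orientation.

    ``event`` maps (record, timeline) to True/False, or None to exclude the
    patient from the comparison's denominator; ``population`` restricts the
    denominator further.  ``group_of`` defaults to the study phase.
    """

    id: str
    event: Callable[[PatientRecord, KidneyStatusTimeline], Optional[bool]]
    group1: str = Phase.observation.value
    group2: str = Phase.intervention.value
    population: Callable[[PatientRecord, KidneyStatusTimeline], bool] = (
        lambda r, t: True
    )
    group_of: Callable[[PatientRecord, KidneyStatusTimeline], str] = (
        lambda r, t: r.phase.value
    )
    family: Optional[str] = None
    description: str = ""


def _zip_timelines(
    cohort: Cohort, timelines: Sequence[KidneyStatusTimeline]
) -> list[tuple[PatientRecord, KidneyStatusTimeline]]:
    by_id = {t.patient_id: t for t in timelines}
    return [(r, by_id[r.patient_id]) for r in cohort]


def run_comparisons(
    cohort: Cohort,
    timelines: Sequence[KidneyStatusTimeline],
    specs: Sequence[ComparisonSpec],
    config: RunConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Evaluate each spec: counts, conditional-MLE OR, matched CI, raw and
    Holm-adjusted p (adjusted within each declared family)."""
    pairs = _zip_timelines(cohort, timelines)
    rows = []
    for spec in specs:
        counts = {spec.group1: [0, 0], spec.group2: [0, 0]}
        for r, t in pairs:
            if not spec.population(r, t):
                continue
            g = spec.group_of(r, t)
            if g not in counts:
                continue
            verdict = spec.event(r, t)
            if verdict is None:
                continue
            counts[g][1] += 1
            counts[g][0] += int(verdict)
        (k1, n1), (k2, n2) = counts[spec.group1], counts[spec.group2]
        table = ContingencyTable2x2.from_events(k1, n1, k2, n2)
        res = exact_or_test(table, config.ci_level, config.fisher_convention)
        rows.append(
            {
                "id": spec.id,
                "family": spec.family,
                "group1": spec.group1,
                "group2": spec.group2,
                "events1": k1,
                "total1": n1,
                "events2": k2,
                "total2": n2,
                "pct1": fmt_pct(k1, n1),
                "pct2": fmt_pct(k2, n2),
                "or_cond_mle": res.or_cond_mle,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_raw": res.p_two_sided,
            }
        )
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = frame["p_raw"]
    for fam, idx in frame.groupby("family", dropna=True).groups.items():
        if fam is not None and len(idx) > 1:
            frame.loc[idx, "p_adjusted"] = holm_adjust(
                frame.loc[idx, "p_raw"].tolist()
            )
    frame["p_rendered"] = frame["p_raw"].map(fmt_p)
    return frame


def default_phase_comparisons() -> list[ComparisonSpec]:
    """The principal observation-vs-intervention contrasts of the analysis."""

    def died(r: PatientRecord, t: KidneyStatusTimeline) -> bool:
        return r.death_time is not None

    return [
        ComparisonSpec(
            id="fluids_given",
            description="received oral or IV fluids",
            event=lambda r, t: r.received_oral_fluids or r.received_iv_fluids,
        ),
        ComparisonSpec(
            id="hospitalization",
            description="admitted >24 h",
            group1=Phase.intervention.value,
            group2=Phase.observation.value,
            event=lambda r, t: r.admitted,
        ),
        ComparisonSpec(
            id="aki_7d",
            description="AKI within 7 days",
            event=lambda r, t: (
                None if t.status_7d is None else t.status_7d is StatusLabel7d.AKI
            ),
        ),
        ComparisonSpec(
            id="overall_mortality",
            description="death during 6-month follow-up",
            event=died,
        ),
        ComparisonSpec(
            id="severe_aki_mortality",
            description="death among severe (stage 2-3) AKI",
            population=lambda r, t: bool(t.aki_7d and t.aki_7d.severe),
            event=died,
        ),
        ComparisonSpec(
            id="lost_by_1mo",
            description="no lab follow-up at or after 1 month (survivors)",
            population=lambda r, t: r.death_time is None
            or r.death_time > MONTH1_H,
            event=lambda r, t: not any(
                s.time >= MONTH1_H * 0.7 for s in r.creatinine_series
            ),
        ),
    ]


def flow_counts(
    cohort: Cohort, timelines: Sequence[KidneyStatusTimeline]
) -> pd.DataFrame:
    """Screening/enrollment flow and status accounting at enrollment and 7 d.

    Node counts nest: each phase's enrollment statuses sum to its enrolled
    count, and 7-day AKI transitions are attributed to the enrollment group
    they arose from.  Screening counts come from cohort provenance when the
    cohort was simulated (redrawn low-risk profiles).
    """
    pairs = _zip_timelines(cohort, timelines)
    screened_out = cohort.provenance.get("screened_low_risk", {})
    rows = []
    for phase in Phase:
        sub = [(r, t) for r, t in pairs if r.phase is phase]
        n_enrolled = len(sub)
        n_low = int(screened_out.get(phase.value, 0))
        rows.append(("screened", phase.value, n_enrolled + n_low))
        rows.append(("excluded_low_risk", phase.value, n_low))
        rows.append(("enrolled", phase.value, n_enrolled))
        for status in ("CKD", "AKD", "NKD", "unclassifiable"):
            n = sum(
                1
                for r, t in sub
                if (
                    t.status_enrollment.value
                    if t.status_enrollment
                    else "unclassifiable"
                )
                == status
            )
            rows.append((f"enrollment_{status}", phase.value, n))
        for origin in ("CKD", "AKD", "NKD"):
            n = sum(
                1
                for r, t in sub
                if t.status_7d is StatusLabel7d.AKI
                and t.origin_group is not None
                and t.origin_group.value == origin
            )
            rows.append((f"aki_from_{origin}", phase.value, n))
        rows.append(
            ("aki_7d", phase.value,
             sum(1 for r, t in sub if t.status_7d is StatusLabel7d.AKI))
        )
    return pd.DataFrame(rows, columns=["node", "phase", "count"])


def mortality_summary(
    cohort: Cohort, timelines: Sequence[KidneyStatusTimeline]
) -> pd.DataFrame:
    """Cumulative deaths by 7-day status, hospitalization stratum and timepoint.

    Denominators are the patients carrying the stratum label; numerators are
    deaths up to each timepoint, so counts are non-decreasing over time and
    strata sum to the overall row.
    """
    pairs = _zip_timelines(cohort, timelines)
    rows = []
    strata = {
        "hospitalized": lambda r: r.admitted,
        "non_hospitalized": lambda r: not r.admitted,
        "overall": lambda r: True,
    }
    for stratum, in_stratum in strata.items():
        for label in ("NKD", "AKD", "CKD", "AKI", "all"):
            members = [
                (r, t)
                for r, t in pairs
                if in_stratum(r)
                and (
                    label == "all"
                    or (t.status_7d is not None and t.status_7d.value == label)
                )
            ]
            den = len(members)
            for tp, hours in _TIMEPOINTS_H.items():
                num = sum(
                    1
                    for r, _ in members
                    if r.death_time is not None and r.death_time <= hours
                )
                rows.append(
                    {
                        "stratum": stratum,
                        "status_7d": label,
                        "timepoint": tp,
                        "deaths": num,
                        "denominator": den,
                        "pct": fmt_pct(num, den),
                    }
                )
    return pd.DataFrame(rows)


def load_printed_comparisons() -> list[dict]:
    """The packaged printed-count regression fixtures."""
    ref = importlib.resources.files("akicohort.data") / "paper_comparisons.yaml"
    payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return payload["comparisons"]


def run_printed_comparisons(level: float = 0.95) -> pd.DataFrame:
    """Recompute every packaged printed comparison from its counts.

    Each row carries the recomputed two-sided exact p (under the convention
    recorded for that entry), the conditional-MLE odds ratio and the matched
    CI, next to the printed values, with rendered strings at the published
    rounding.
    """
    rows = []
    for spec in load_printed_comparisons():
        table = ContingencyTable2x2.from_events(
            spec["events1"], spec["total1"], spec["events2"], spec["total2"]
        )
        convention = FisherConvention(spec.get("p_convention", "minlike"))
        res = exact_or_test(table, level, convention)
        printed_ci = spec.get("printed_ci")
        rows.append(
            {
                "id": spec["id"],
                "group1": spec["group1"],
                "group2": spec["group2"],
                "events1": spec["events1"],
                "total1": spec["total1"],
                "events2": spec["events2"],
                "total2": spec["total2"],
                "p": res.p_two_sided,
                "p_rendered": fmt_p(res.p_two_sided),
                "printed_p": spec["printed_p"],
                "or_cond_mle": res.or_cond_mle,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "ci_rendered": f"{res.ci_low:.2f}, {res.ci_high:.2f}"
                if math.isfinite(res.ci_high)
                else f"{res.ci_low:.2f}, inf",
                "printed_ci_low": printed_ci[0] if printed_ci else math.nan,
                "printed_ci_high": printed_ci[1] if printed_ci else math.nan,
            }
        )
    return pd.DataFrame(rows)
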