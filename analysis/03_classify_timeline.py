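#!/usr/bin/env python
"""Run the kidney-status state machine over the cohort.

Produces results/timeline.csv (one row per patient: enrollment status,
7-day AKI with criterion and KDIGO stage, 1-month recovery, 3/6-month CKD
fields) and results/flow.csv (the screening/enrollment/status flow), and
prints the headline accounting: status mixture at enrollment and AKI
transitions at 7 days by originating group.
"""
import argparse
from pathlib import Path

from akicohort.config import RunConfig
from akicohort.io import read_cohort
from akicohort.report import flow_counts
from akicohort.status import classify_cohort, timelines_to_frame

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = read_cohort(args.cohort)
timelines = classify_cohort(cohort, RunConfig())
frame = timelines_to_frame(timelines)
frame.to_csv(args.out / "timeline.csv", index=False)
flow = flow_counts(cohort, timelines)
flow.to_csv(args.out / "flow.csv", index=False)

n = len(frame)
for status in ("AKD", "CKD", "NKD"):
    k = (frame.status_enrollment == status).sum()
    print(f"enrollment {status}: {k} ({100 * k / n:.0f}%)")
aki = frame[frame.aki_detected]
print(f"AKI within 7 days: {len(aki)} ({100 * len(aki) / n:.0f}%)")
for origin in ("AKD", "CKD", "NKD"):
    sub = frame[frame.status_enrollment == origin]
    k = (sub.status_7d == "AKI").sum()
    print(f"  from {origin}: {k}/{len(sub)} ({100 * k / max(len(sub), 1):.0f}%)")
decline = aki.aki_criterion.isin(["fall_48h_abs", "fall_7d_ratio"]).sum()
print(f"AKI detected by creatinine decline: {decline} "
      f"({100 * decline / max(len(aki), 1):.1f}% of AKI)")
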