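# akicohort

Analysis pipeline for **community-acquired acute kidney injury (AKI)
recognition programs** in low-resource settings: cohorts enrolled at primary
healthcare centers by a symptom-based risk score, characterized with
point-of-care (POC) serum creatinine and urine dipstick testing, followed for
six months, and compared across an observation and an intervention phase.
It is written for epidemiologists and biostatisticians who need the full
chain — triage score, kidney-status classification, exact small-table
inference — as tested, reusable code, together with a calibrated synthetic
cohort generator so that every stage can be exercised without patient-level
data (which studies of this kind typically cannot deposit).

## What it computes

**Risk score.** Twelve presentation symptoms (decreased urine output,
hypotension/shock, coma, jaundice, anemia, confusion, dyspnea, respiratory
infection symptoms, petechiae, ecchymosis, bleeding, and hypertension in
pregnant women) score one point each; 0–2 is low risk, 3–5 moderate, ≥6
high. Moderate- and high-risk patients are enrolled.

**Kidney status.** At enrollment each patient is classified with precedence
CKD > AKD > NKD:

- **CKD** — known history, or a baseline creatinine within 12 months giving
  eGFR < 60 ml/min/1.73 m² (2009 CKD-EPI creatinine equation, race
  coefficient off by default);
- **AKD** — enrollment eGFR < 60 or dipstick proteinuria ≥ 1+ without known
  chronicity;
- **NKD** — neither.

**AKI within 7 days** uses an increase-*or-decline* creatinine criterion:

    ΔScr ≥ 26.5 μmol/l within 48 h (rise or fall), or
    Scr > 1.5 × reference within 7 d (rise), or
    enrollment Scr > 1.5 × later Scr within 7 d (decline),

staged through the KDIGO bands (ratio >1.5–2.0 → stage 1, >2.0–3.0 → 2,
>3.0 or ≥ 353.6 μmol/l with a rise or dialysis → 3). The decline arm
catches resolving community AKI that a rise-only rule misses. Recovery at
1 month is complete (≤ reference), partial (between reference and peak) or
none (≥ peak, dialysis-dependent, or eGFR < 15); 3/6-month visits yield
new-onset CKD (eGFR < 60 in non-CKD strata) and CKD progression (eGFR below
the enrollment value in the CKD stratum).

**Phase inference.** Every 2×2 contrast uses the two-sided Fisher exact test
under the minimum-likelihood ordering, the conditional maximum-likelihood
odds ratio (root of the noncentral hypergeometric mean equation), and the
**Fay matched exact CI** — the interval of odds ratios not rejected by that
same two-sided test, so the test and interval never contradict. Families of
pairwise comparisons are Holm-adjusted; continuous contrasts use t /
Mann–Whitney U tests with a Kolmogorov–Smirnov normality check.

**Simulator.** `SimulationConfig` defaults encode the published cohort
structure: 2,101 enrollees split 978/1,123 by phase; 9.4/57/34% CKD/AKD/NKD
at enrollment; conditional 7-day AKI probabilities 47/37/14%; 41.5% of AKI
detected by decline; stage mixture 40/22/38%; 27%/18% loss to follow-up by
1 month per phase; mortality 22.6/16.8/13.5/5.9% by 7-day status; 7%
multiplicative POC measurement noise. Ground-truth labels are retained so
recovery of every configured proportion can be verified.

## Worked example

```
$ python analysis/01_simulate_cohort.py --seed 0
enrolled 2101 patients (1028 observation / 1073 intervention)
$ python analysis/03_classify_timeline.py
enrollment AKD: 1195 (57%)
enrollment CKD: 187 (9%)
enrollment NKD: 719 (34%)
AKI within 7 days: 637 (30%)
  from AKD: 449/1195 (38%)
  from CKD: 90/187 (48%)
  from NKD: 98/719 (14%)
AKI detected by creatinine decline: 261 (41.0% of AKI)
```

That is: under the default calibration, 57% of enrollees present with acute
kidney disease, 30% meet the AKI criterion within a week (about half of CKD
patients, a third of AKD patients, a seventh of NKD patients), and two in
five AKI episodes are caught only because the decline arm of the criterion
exists. Exact inference on published counts:

```python
>>> from akicohort import ContingencyTable2x2, exact_or_test
>>> t = ContingencyTable2x2.from_events(27, 135, 21, 178)   # severe-AKI deaths
>>> r = exact_or_test(t)
>>> round(r.p_two_sided, 3), round(r.or_cond_mle, 2), (round(r.ci_low, 2), round(r.ci_high, 2))
(0.057, 1.86, (0.98, 3.52))
```

— a mortality odds ratio of 1.86 for the observation phase whose matched 95%
CI just includes 1, agreeing with the exact p of 0.057.

The same stages are available as a CLI (`akicohort simulate|score|classify|
analyze|report|run`) and as the numbered drivers under `analysis/`, which
write their tables to `results/`.

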