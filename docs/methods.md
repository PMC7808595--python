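# Methods

## Classification model

All rules operate on serum creatinine in μmol/l and real-valued time in
hours since enrollment (calendar dates are converted at the I/O boundary;
the mg/dl conversion constant is 88.42). Scheduled visits are resolved by
windows around their nominal times — 48 h: (0, 60 h]; day 7: [120, 240 h];
month 1: [21, 45 d]; month 3: [60, 135 d]; month 6: [150, 225 d] — with a
sample assigned to the nearest containing window, because field follow-up
in community programs is irregular. The windows are configuration, not
constants.

**Enrollment status** (precedence CKD > AKD > NKD): CKD by known history or
a prior baseline within 12 months with CKD-EPI eGFR < 60; AKD by enrollment
eGFR < 60 or dipstick proteinuria ≥ 1+ (trace is negative); NKD otherwise.
A missing enrollment creatinine yields an explicit *not classifiable*
status rather than an exception, so one bad record cannot halt a cohort
run.

**eGFR** uses the 2009 CKD-EPI creatinine equation
(141 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.209 · 0.993^age · 1.018 [female] ·
1.159 [optional race coefficient, off by default]). It is an adult
equation, so eGFR-based rules apply to adults (≥ 18 y) only; children are
classified by history, dipstick and creatinine-change criteria, and their
eGFR-gated follow-up fields are *not assessable*. A bedside-Schwartz
fallback (36.5 · height/Scr) is available behind `egfr.pediatric =
schwartz` for data that carry height; it is never applied implicitly.
Threshold comparisons always use the unrounded eGFR.

**AKI detection** scans all samples in [0 h, end of the day-7 window]. Four
criteria, recorded as the first satisfied in order: (a) a rise ≥ 26.5
μmol/l between any two samples ≤ 48 h apart; (b) any sample > 1.5 × the
reference creatinine; (c) a fall ≥ 26.5 μmol/l within 48 h; (d) enrollment
creatinine > 1.5 × a later sample. The reference for rises is the
enrollment value, except for CKD patients with a prior baseline, whose
baseline serves as reference; decline criteria always compare against the
enrollment value. "Decline to > 1.5 times" is operationalized as
enrollment > 1.5 × later — the reading that mirrors the rise criterion.
Staging uses r = max(peak/reference, enrollment/nadir) through the KDIGO
bands, open below and closed above (r = 2.0 → stage 1, r = 3.0 → stage 2);
absolute-change-only events are stage 1; any rise reaching 353.6 μmol/l, or
dialysis, forces stage 3. Decline-detected events are staged by
enrollment/nadir through the same bands (KDIGO does not define this case);
`decline_staging = always_stage1` gives the conservative alternative. When
a 48 h rise occurs entirely below a chronic baseline, the episode reference
falls back to the enrollment value so the recorded extreme/reference pair
stays coherent. Urine-output criteria are not implemented: the data
contract carries no urine-output measurements.

**7-day status** is AKI (annotated with the originating enrollment group)
when detection fires, else the enrollment label carried forward. Recovery
at 1 month: *none* if dialysis-dependent or eGFR < 15; *complete* if the
1-month creatinine is at or below the reference; *partial* if between
reference and peak; *none* if at or above peak; *not assessable* without a
1-month sample. New-onset CKD (non-CKD strata) is eGFR < 60 at 3 or 6
months; CKD progression (CKD stratum) is a visit eGFR below the enrollment
eGFR; acute kidney disease arising in patients still NKD at 7 days is
flagged from a 1-month eGFR < 60 or 1-month proteinuria. Every timepoint's
denominator contains only patients with the required in-window measurement:
loss to follow-up shrinks denominators and is never imputed.

## Exact inference

Two-sided Fisher p-values use the minimum-likelihood ordering: the sum of
hypergeometric outcome probabilities not exceeding the observed one, with a
relative tie slack of 1e-7 because floating-point ties are real at these
table sizes. This is the ordering whose inversion yields the Fay *matched*
interval, so p ≤ α exactly when 1 falls outside the CI — a property the
test suite checks on 1,000 random tables with zero tolerated violations.
The doubled-one-sided convention is available behind `fisher_convention`
(which two-sided convention the original software used is not knowable from
a published table; one published p-value in the packaged fixture reproduces
only under doubling and is recorded as such there). The odds-ratio point
estimate is the conditional MLE — the root of the noncentral
hypergeometric mean equation, 0 or +∞ at zero cells. CI endpoints invert
the two-sided test by a vectorized grid scan over log-odds ∈ [ln 1e-10,
ln 1e10] followed by bisection to 1e-8 on the log scale; endpoints are the
infimum and supremum of the non-rejected set, and rounding to the published
2 decimals happens only at the presentation layer. Degenerate margins give
p = 1 with a warning; empty strata are dropped from pairwise families with
a warning, and Holm adjustment (step-down, via statsmodels) is applied
within each declared comparison family.

Mann–Whitney U is exact for untied samples of ≤ 20 per group and uses the
tie-corrected normal approximation otherwise; normality is checked per
sample by Kolmogorov–Smirnov against a normal with the sample's own
mean/SD. With zero variance in both samples the t test is undefined and
returns NaN with a warning rather than killing the rank test.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a two-phase
community-AKI cohort, not renal physiology. Each patient receives: a phase
(46.6% observation); age (13% children; adult ages log-normal, median 47,
truncated to [18, 96]); sex (53.2% female); an enrollment status from the
(9.4, 57.0, 33.6)% CKD/AKD/NKD mixture; a conditional 7-day AKI indicator
(47/37/14% by status); and, for AKI, a decline-presentation indicator
(41.5%) and a KDIGO stage from (40.1, 22.0, 37.9)%. Symptom profiles are
drawn from per-symptom prevalences (status-scaled) and redrawn until the
risk score reaches the enrollment cut of 3; redraws are tallied as
screened-but-excluded low-risk patients, which is what the flow table
reports as the screening funnel.

Creatinine trajectories are piecewise templates over the scheduled visits:
stable (constant), rising-to-plateau (peak reached by 48 h and held through
day 7), and resolving-decline (geometric descent to a day-7 nadir).
Template amplitudes are drawn to *guarantee or avoid* the classification
thresholds the assigned label requires: stable reduced-eGFR baselines
target eGFR 40–54 and are capped at 145 μmol/l so that, at the default 7%
measurement CV, a stable pair rarely crosses the 26.5 μmol/l criterion and
a stage-2 peak (ratio 2.25–2.7, capped at 335 μmol/l) cannot cross the
353.6 μmol/l absolute stage-3 threshold; stage-1 rises on baselines ≥ 80
μmol/l in admitted patients use a supra-threshold absolute jump (+45–65
μmol/l) with ratio below 1.9, while low-baseline or non-admitted stage-1
events use ratio targets 1.70–1.88 (non-admitted patients have no 48 h
sample — it is only drawn for admitted patients, as in practice — so their
detection must ride the 7-day ratio). Stage-3 targets are ratios 3.4–4.8.
Children's AKD carries proteinuria (the structural criterion) because the
adult eGFR rule cannot apply to them. Follow-up course: recovery mixture
(complete/partial/none = 60/20/20%) among rise-AKI; post-AKI persistent
dysfunction at 3/6 months with probability 18.4%; persistent low eGFR in
37%-of-AKD-without-AKI at 33–34%; CKD progression at 54.5%; AKD appearing
on NKD at 4.1%.

**Ground truth** is defined as the classifier's output on the noiseless,
dropout-free but death-censored trajectory: death is a real event, measured
noise and missed visits are observation corruptions. Deaths are drawn per
7-day status (22.6/16.8/13.5/5.9%) with times after the first week, so the
7-day assessment of decedents is complete — a deliberate simplification
(real community cohorts lose some patients before day 7). Lab follow-up is
censored at a dropout time (probability 27%/18% by phase of being lost
before 1 month, uniform over days 3–30; a further 45% of the remainder lost
between months 1 and 6); vital status is always ascertained, emulating
phone/home-visit tracing, so the 1-month lost fraction is estimated among
patients alive at 30 days and is unbiased for the configured probability.
An `informative_dropout_multiplier` scales dropout for patients with kidney
dysfunction to probe the bias that outcome-dependent loss to follow-up
would induce; it defaults to 1 (independent dropout). Measurement noise is
multiplicative log-normal with mean 1 (CV default 7%, a plausible POC
creatinine figure); all randomness flows from one seed through two child
streams, so varying the CV re-uses identical latent cohorts and noise
deviates (common random numbers), which is what makes the
accuracy-vs-noise monotonicity test sharp.

**What passing tests do and do not show.** Noiseless identifiability (100%
label agreement at CV 0, no dropout) and 3-binomial-SE parameter recovery
at n = 5,000 under the default CV show the pipeline is a consistent
estimator of the generator's structure — they cannot certify behavior on
real POC data, whose error model (device rounding, hematocrit effects,
operator variation) and trajectory shapes are richer than these templates.
Under 7% noise a few percent of stage-1 ratio events cross the 2.0 band
edge (stage 2 is recovered ~3 points above its configured share) and
stable high-creatinine patients occasionally trip the absolute-change
criterion (~1–2 points of extra AKI in the CKD/AKD strata); both effects
stay inside the 3-SE acceptance bands and are properties of the criterion
itself, not bugs.

## Numerical and design choices

- A risk score of exactly 6 sits between the published "moderate (3–5)" and
  "high (>6)" bands; it is classified high by default (`score6_category`
  switches it), and enrollment eligibility is unaffected either way.
- The admission flag follows the recorded disposition when present and the
  > 24 h length-of-stay rule only as a fallback (transfers can violate the
  duration heuristic).
- Dialysis has no timestamp in the data contract, so the stage-3 dialysis
  condition uses the dialysis flag, and 1-month dialysis dependence is an
  explicit argument of `classify_recovery` (False at cohort level).
- Missing values are empty CSV fields, never sentinels; floats are written
  at full precision so write→read is the identity.
- Printed-comparison fixtures packaged with the library pin each published
  2×2 contrast's counts *and orientation* — the published tables are not
  direction-consistent, so orientation is data. One published contrast
  (patients sent home) prints a negative "OR CI", impossible for an odds
  ratio (an apparent transcription swap); it is excluded from the fixture.
- Rendering: percentages to 1 decimal, p to 3 decimals ("<0.001" below),
  CI endpoints to 2 decimals.

## Problem sizes

The acceptance surface uses: the packaged printed 2×2 tables (desk scale,
< 1 s each); exhaustive Fisher-vs-enumeration over all 2×2 tables with
n ≤ 60 (≈ 6 × 10⁵ tables); 1,000 random tables for the test–interval
matching property; 10,000 random short series for the AKI detector oracle;
and simulated cohorts of n = 5,000 (parameter recovery) and n = 1,500
(noiseless identifiability). These sizes give every binomial check a
standard error comfortably below the effects being verified.

## Known limitations

- Trajectory templates are phenomenological; no creatinine kinetics, no
  within-week sampling beyond the scheduled visits, no device rounding.
- The simulator ties AKI risk to enrollment status but not to phase, so
  phase contrasts of AKI incidence are null in synthetic cohorts by
  construction (care-process contrasts — fluids, admission, dropout — do
  differ by phase).
- Pediatric eGFR is deliberately unhandled by default; enabling the
  Schwartz fallback requires height data the standard schema does not
  carry.
- Recovery is assessed against the rise reference; for decline-detected
  events reference and peak coincide at the enrollment value, so partial
  recovery is not a reachable class for them.
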