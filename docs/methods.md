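# Methods

This note documents the models and procedures implemented in `actifit`,
the assumptions behind them, the calibration of the synthetic cohort, and
what the tests do and do not establish.

## Scientific setting

The package models a cross-sectional study design common in physical-
activity epidemiology: a cohort of young adults (~19–20 y) wears a
uniaxial hip accelerometer for 7 days and performs a submaximal ramped
step test, and the analysis asks how objectively measured activity,
body-mass index and sex relate to cardiorespiratory fitness.  Since no
participant-level data are deposited for such cohorts, the package ships
a synthetic-cohort generator whose ground truth is calibrated to the
published cohort statistics, and every analysis stage is validated as a
parameter-recovery experiment against that truth.

## Accelerometry processing

Raw 5-s counts are reintegrated to counts per minute (cpm), because the
published intensity cut-points are defined on the 60-s scale.  The stream
is snapped forward to the next whole clock minute and a trailing partial
minute is dropped.  The stages, in order:

1. **Non-wear**: any maximal run of *strictly more than* 90 consecutive
   zero-count minutes is flagged non-wear.  "Continuous" is strict — a
   single non-zero minute breaks the run.  Detection runs on the full
   minute stream *before* sleep removal, so an overnight zero run and an
   adjacent morning non-wear period merge naturally.
2. **Sleep window**: minutes with clock time in [00:00, 06:00) are
   removed.  The conventional description "between 12 pm and 6 am" is
   interpreted as midnight–06:00: removing noon-to-6am would delete 75%
   of the day including prime waking hours, contradicting the purpose of
   the rule (participants who slept in the device).  The noon variant
   remains available through `sleep_window`.
3. **Cut-points** on integer cpm: sedentary [0, 99], light [100, 2019],
   moderate [2020, 5998], vigorous [5999, ∞).  MVPA = moderate +
   vigorous.
4. **Bouts**: maximal runs of ≥10 consecutive MVPA minutes, with no
   interruption allowance; sleep or non-wear minutes break a run.
5. **Validity**: a day is valid with ≥500 wear minutes (evaluated after
   sleep removal, since removed sleep cannot count as wear — switchable
   via `wear_requirement_after_sleep_removal`); a participant is valid
   with ≥3 valid days.  Participant values are means over valid days.
6. **Guidelines**: CDC-active if mean daily MVPA ≥ 150/7 min *or* mean
   daily vigorous ≥ 75/7 min (bouts not required); WHO-active if mean
   daily *bouted* MVPA ≥ 30 min.  Under the defaults 30 > 150/7, so
   WHO-active implies CDC-active; the converse fails exactly when MVPA is
   accumulated sporadically, which is the contrast the synthetic
   behaviour model is built to exercise.

## Step-test VO2max estimation

The protocol is a fixed 0.20-m step with a cadence prompt rising linearly
from 15 to 33 steps/min over 8 minutes, followed by 2 minutes of seated
recovery; heart rate is summarised in 15-s bins.  Predicted workload at
ramp time *t* is the ACSM stepping equation in gross per-kg terms,

    VO2(t) = 0.2·f(t) + 1.33·1.8·h·f(t) + 3.5   [mlO2/kg/min],

with f the cadence and h the step height.  HR above resting is regressed
on predicted workload over clean ramp bins (ordinary least squares), and
the line is extrapolated to the age-predicted maximal heart rate
(Tanaka: 208 − 0.7·age, configurable):

    VO2max = (HRmax − HRrest − intercept) / slope.

Because the workload axis already contains the 3.5 resting term, the
extrapolated workload at maximal HR *is* the VO2max estimate; no further
offset is added.  Estimates are clipped to [10, 90] mlO2/kg/min with a
flag.  A deterministic artifact rule stands in for visual ECG review:
bins outside [30, 220] bpm, or jumping >30 bpm from the previous clean
bin, are masked.  Tests shorter than 4 minutes, or with fewer than 6
clean ramp bins, are invalid.  The 60-s recovery HR drop is computed and
reported as a diagnostic; its weight in the estimate defaults to zero
because no reproducible formula exists for folding recovery HR into the
extrapolation, and the hook (`recovery_weight`) is documented as an
extension point rather than inventing one.

Fitness category is the sex-specific median split of estimated VO2max,
with values exactly at the median labelled fit.

## Synthetic cohort

### Behaviour model

Each day is an alternating-renewal sequence over six minute-level states
(sleep, non-wear, sedentary, light, moderate, vigorous).  Sleep occupies
the first 360 minutes (inside the removal window, so generator and
pipeline agree about it).  Per-participant daily dwell targets are drawn
once per person; per-day budgets then vary around them with Poisson
noise, so long-run day means equal the targets exactly.  Budgets are laid
down as runs: sedentary runs of 10–40 min and light runs of 3–15 min form
a backbone, and MVPA runs are inserted into distinct gaps of that
backbone so short runs cannot accidentally merge into bouts.  A
per-participant *bout fraction* g sends that share of MVPA minutes into
runs of 10–25 consecutive minutes; the rest is scattered in 1–6-min
(moderate) and 1–4-min (vigorous) runs.  Non-wear is one contiguous block
of ≥100 minutes, so the >90-min zero-run detector recovers it exactly.

Minute counts are truncated lognormals held strictly inside the labelled
state's cut-point band (sedentary median 30 cpm, light 500, moderate
3200, vigorous 6800; sleep and non-wear are zero), each minute divided
multinomially over twelve 5-s epochs.  Band truncation makes minute
classification exactly label-recovering, which the property tests
exploit; the price is that the synthetic data contain no boundary-
straddling minutes, so the tests say nothing about cut-point
misclassification on real data.  Run-length and count-distribution
shapes (geometric-ish runs, lognormal counts) are pragmatic stand-ins —
the published record contains no distributional information at this
resolution.

### Calibration to the reference cohort

All calibration constants live in `CohortConfig` defaults and were fixed
once, from the published statistics, before any end-to-end run:

* **Anthropometry**: per-sex normal heights and weights with means
  1.72/1.60 m and 62.5/61.3 kg and SDs back-computed from the published
  95% CIs (n = 218 M / 191 F), truncated to plausible ranges.
* **MVPA targets** ~ Normal clipped at 2 min/day.  Medians are the
  published 83 (M) / 43 (F) min/day; the SDs are identified by the CDC
  inactivity shares (4% of males, 17% of females below the prorated
  150/7 ≈ 21.43 min/day threshold):
  sd = (median − 150/7) / Φ⁻¹(active share), i.e. 35.17 (M), 22.61 (F).
  Clipping (not truncation) at 2 preserves both the median and the
  upper-tail probabilities this identification uses.
* **Sedentary targets** ~ Normal(541, 45) / Normal(575, 45); light ~
  Normal(128, 25) / Normal(132, 25); non-wear is the residual of the
  1080-min waking budget (~328/330 min), floored at 100 min.  The 45- and
  25-min SDs are realism choices (the source reports no dispersions); the
  independence of sedentary and MVPA draws keeps their cohort correlation
  far from the collinearity screen's 0.7 threshold.
* **Vigorous fraction** of MVPA ~ lognormal with median 0.060 (M) /
  0.0233 (F), reproducing the published vigorous medians of 5 and 1
  min/day as the product with the MVPA medians.
* **Bout fraction** g ~ Beta(2, b) per sex, with b = 3.75 (M) / 2.53 (F)
  solved by Monte Carlo so that 40% of males and 20% of females average
  ≥30 bouted MVPA min/day through the full pipeline.
* **True VO2max**: vo2 = β₀ + 0.03·MVPA − 0.30·BMI + 7.52·male + ε,
  clipped to [15, 80].  The slopes are the published regression
  coefficients.  β₀ = 38.27 solves the male mean of 41.9 given the male
  covariate means (the implied female mean, 32.3, lands within 0.3 of the
  published 32.6 without further tuning).  ε ~ N(0, 4.05): the published
  R² of 0.60 describes *measured* VO2max, so the generative residual
  satisfies σ² = var(linear predictor)·(0.4/0.6) − σ²_est, where
  var(linear predictor) = 25.6 by Monte Carlo over the 137:119 sex
  mixture and σ²_est = 0.62 is the measured step-test estimation-error
  variance at the default 3 bpm HR noise.
* **Step test**: HR(t) = HRrest + (VO2(t) − 3.5)·(HRmax − HRrest)/
  (VO2max − 3.5) + N(0, 3 bpm) on the ramp — the exact inverse of the
  estimator, so noise-free traces invert to machine precision — and an
  exponential decay toward resting (τ = 40 s) in recovery.  Resting HR ~
  N(65, 8) bpm; ages uniform on {19, 20}.

### What the generator does not emulate

Circadian structure beyond the sleep window; seasonality and weekday/
weekend contrast; boundary-straddling count distributions; correlation
between behaviour and anthropometry beyond what the VO2max model induces;
triaxial acceleration and ECG waveforms (the artifact rule operates on
HR summaries).  Passing recovery tests therefore demonstrates the
correctness of the processing chain under the stated generative model,
not robustness to the messiness of field recordings.

## Statistics layer

Student's t (pooled variance) with t-based 95% CIs for parametric
variables; Mann-Whitney U (exact for n ≤ 20 without ties, otherwise
normal approximation with tie correction) with seeded bootstrap
percentile CIs for medians (2000 replicates — the source's median CI
method is unknown, so CI widths are not reproduction targets); Pearson
chi-squared without continuity correction for categorical splits.  OLS
throughout (statsmodels); the multiple regression applies a pairwise
|r| > 0.7 collinearity screen in predictor order, which operationalises
the reference exclusion of height and weight once BMI is in the model.
The univariate significance gate for entry into the multiple model uses
p < 0.05.  Regression margins are model predictions per factor level with
the covariate held at its grand mean.  One-way ANOVA per sex across BMI
categories (WHO partition at 18.5/25/30, with overweight excluding obese)
uses Bonferroni-multiplied pairwise t comparisons, multiplying by the
number of comparisons actually performed.

## Numerical and design choices

* Timestamps are naive local clock times; days are calendar dates and a
  recording spanning midnight is split by date (non-wear detection runs
  per recording before the split).
* Unrecorded minutes are non-wear and break zero runs.
* Exact threshold semantics are half-open everywhere and asserted at the
  boundary in tests (90 vs 91 zero minutes, 9 vs 10 bout minutes, 499 vs
  500 wear minutes, cpm 99/100, 2019/2020, 5998/5999, BMI 18.5/25/30,
  test duration 239/240 s).
* All randomness flows through explicit `numpy.random.Generator` objects;
  cohort generation is byte-reproducible from its seed.

## Reproduction experiment sizes

Cohort-level quantities (medians, guideline percentages, margins,
estimated-VO2max medians) are measured on the default 256-participant
cohort; because a single cohort's medians carry several min/day of
sampling noise (the female sedentary median has an SE near 5 min/day),
the reported values are Monte-Carlo means over 10 replicate cohorts with
consecutive seeds.  Coefficient recovery uses one n = 5000 cohort at the
same 137:119 sex ratio, processed through the identical measurement
chain, with agreement judged within 2 standard errors.  Step-test error
statistics use 200 simulated tests.

## Known limitations

The calibration identifies dispersion from adherence percentages under a
parametric (clipped-normal) assumption; a different shape would give
different tails with the same medians.  The published MVPA margins by
fitness category (73 vs 58 min/day) are not calibration inputs; the
emergent values here centre near 69 vs 61 — the published regression
coefficients, R², medians and adherence shares do not jointly pin the
fit/unfit contrast any tighter.  The recovery-HR term of the original
branched estimation method is reported but unweighted.  The artifact rule
is a stand-in for expert review and has not been validated against real
ECG noise.
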