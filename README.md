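# actifit

Accelerometer activity processing, submaximal step-test VO2max
estimation, and sex-stratified cohort statistics — packaged with a
calibrated synthetic-cohort generator so the whole analysis chain is
testable end to end against known ground truth.

## The problem

Physical-activity epidemiology studies of young adults typically combine
three measurements: 7 days of hip-worn uniaxial accelerometer counts, a
submaximal ramped step test, and basic anthropometry.  Turning the raw
counts into publishable quantities involves a long chain of conventions —
epoch reintegration, non-wear detection, sleep-window removal, intensity
cut-points, bout detection, wear-time validity screens, guideline
classification — and the fitness estimate requires extrapolating a
submaximal heart-rate response to an age-predicted maximum.  Each step
has threshold semantics that are easy to get subtly wrong and hard to
check without ground truth.  `actifit` implements the chain as a tested
library, and, because cohorts like this rarely deposit participant-level
data, ships a generator that emulates all three inputs with known truth
calibrated to published cohort statistics.

## The processing chain

* **Accelerometry** (`actifit.accel`): 5-s counts → counts per minute
  (cpm) → non-wear (>90 min of continuous zeros) → sleep window
  [00:00, 06:00) removed → cut-points (sedentary <100, light 100–2019,
  moderate 2020–5998, vigorous ≥5999 cpm) → strict ≥10-consecutive-minute
  MVPA bouts → valid days (≥500 wear min) and participants (≥3 valid
  days) → CDC (daily MVPA ≥ 150/7 min or vigorous ≥ 75/7 min) and WHO
  (≥30 min/day of *bouted* MVPA) classifications.
* **Step test** (`actifit.steptest`): heart rate in 15-s bins, automated
  artifact masking, OLS of HR above resting on the ACSM stepping workload
  `0.2·f + 1.33·1.8·h·f + 3.5` over a 15→33 steps/min ramp on a 0.20-m
  step, extrapolated to the Tanaka maximum `208 − 0.7·age`:
  `VO2max = (HRmax − HRrest − intercept)/slope` in mlO2/kg/min.
* **Statistics** (`actifit.stats`): sex-stratified descriptives with CIs,
  t / Mann-Whitney / chi-squared comparisons, univariate and multiple OLS
  of VO2max with a collinearity screen, BMI-adjusted regression margins
  of MVPA by fitness category (sex-specific median split), and ANOVA of
  VO2max across WHO BMI categories with Bonferroni post hoc tests.
* **Synthetic cohort** (`actifit.synthetic`): an alternating-renewal
  behaviour model over {sleep, nonwear, sedentary, light, moderate,
  vigorous}, band-truncated lognormal counts split multinomially into 5-s
  epochs, a generative linear VO2max model
  `β0 + 0.03·MVPA − 0.30·BMI + 7.52·male + ε`, and simulated step-test
  HR traces that the estimator inverts exactly when noise-free.
  See `docs/methods.md` for the model and its calibration.

## Worked example

The numbered scripts under `analysis/` run the study pipeline on the
packaged default cohort (137 males, 119 females, seed 1234; ~120 MB of
count files are written under `scratch/`):

```
python analysis/01_simulate_cohort.py
python analysis/02_process_accelerometry.py
python analysis/03_estimate_fitness.py
python analysis/04_cohort_statistics.py
```

The final script prints, among other output:

```
mvpa_min        M   81.00  F   43.29  p=4.8e-19
sedentary_min   M  545.71  F  567.43  p=0.00048
vo2max          M   42.17  F   32.49  p=4.1e-40
multiple regression of VO2max (r2=0.58, n=256):
  sedentary_min       0.002
  mvpa_min            0.035
  bmi                -0.341
  sex                 7.382
BMI-adjusted MVPA margins: fit 69, unfit 61 min/day
```

Read: males accumulate roughly twice the daily MVPA of females (medians
81 vs 43 min/day) and are fitter (estimated VO2max 42.2 vs 32.5
mlO2/kg/min), females sit more (567 vs 546 min/day), and in the joint
model MVPA (+0.035 per min/day) and BMI (−0.34 per kg/m²) are
independently associated with fitness while sedentary time is not — each
fitted coefficient sitting within sampling error of the generative values
(0.03, −0.30, 7.52).  Fit participants (at or above their sex's median
VO2max) average ~8 more MVPA min/day than unfit ones at the same BMI.

The same flow is available in memory without file I/O:

```python
from actifit import process_cohort
tables = process_cohort(seed=1234)
print(tables["cohort"][["sex", "mvpa_min", "vo2max"]].groupby("sex").median())
```

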