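"""Synthetic cohort with known ground truth.

Generates the three inputs the analysis needs — anthropometry, 7-day 5-s
accelerometer count streams, and submaximal step-test heart-rate traces —
for a cohort of young adults, so every downstream stage can be tested
against a known generative truth without any data download.

Behaviour model
---------------
Each day is an alternating-renewal sequence of minute-level states
{sleep, nonwear, sedentary, light, moderate, vigorous}.  Sleep occupies
the start of the 00:00-06:00 window; the waking 1080 minutes are tiled
with runs whose per-state daily budgets are drawn around participant-level
targets (Poisson day-to-day variation, so long-run day means equal the
targets exactly).  Moderate/vigorous time is split into long runs (>=10
consecutive minutes, controlled by a per-participant bout fraction) and
short sporadic runs (<10 min), which creates the bouted-vs-total MVPA
contrast that separates the WHO rule from the CDC rule.  Non-wear is one
contiguous block of at least 100 minutes so the >90-min zero-run detector
recovers it exactly.

Counts are drawn per minute from a lognormal truncated to the labelled
state's cut-point band (so classification can recover the labels exactly)
and divided across twelve 5-s epochs multinomially.

Calibration
-----------
The default profiles are calibrated so that the *processed* cohort
reproduces the reference cohort statistics this package models:

* daily-MVPA targets ~ Normal clipped at 2 min/day, with the sex medians
  (83 / 43 min) and SDs chosen so that the share of participants below the
  prorated CDC threshold of 150/7 min/day equals the reported inactive
  fractions (4% of males, 17% of females):
  sd_m = (83 - 150/7) / z(0.96) = 35.17, sd_f = (43 - 150/7) / z(0.83) = 22.61;
* sedentary targets ~ Normal(541, 45) males / Normal(575, 45) females,
  light ~ Normal(128, 25) / Normal(132, 25); non-wear is the residual of
  the 1080-min waking budget (~328/330 min);
* the bout fraction (share of MVPA minutes laid down in >=10-min runs)
  ~ Beta(2, b) per sex, with b fixed by Monte Carlo so that 40% of males
  and 20% of females average >=30 bouted MVPA min/day;
* true VO2max follows the linear model
  vo2 = beta0 + 0.03*MVPA + (-0.30)*BMI + 7.52*[male] + N(0, sd_resid),
  with beta0 solving the male mean of 41.9 mlO2/kg/min given the male
  covariate means, and sd_resid sized so that the fitted model on
  *measured* (step-test estimated, 3 bpm HR noise) VO2max has R^2 = 0.60:
  sd_resid^2 = var_explained * (0.4/0.6) - var_estimation_error.

The derived constants are frozen below with their derivations; see
docs/methods.md for the full account.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date, datetime, timedelta
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .config import RunConfig
from .io import CountFile, StepTestRecord, write_count_file, write_step_test
from .steptest import predict_max_hr, predict_workload_vo2

# state codes: first four match accel intensity codes
SEDENTARY, LIGHT, MODERATE, VIGOROUS, SLEEP, NONWEAR = 0, 1, 2, 3, 4, 5
STATE_NAMES = {SEDENTARY: "sedentary", LIGHT: "light", MODERATE: "moderate",
               VIGOROUS: "vigorous", SLEEP: "sleep", NONWEAR: "nonwear"}

RESTING_VO2 = 3.5  # mlO2/kg/min


@dataclass(frozen=True)
class StateCounts:
    """Truncated-lognormal 60-s count distribution for one state."""
    median_cpm: float
    sigma: float
    lo: int
    hi: int


# per-state count bands sit strictly inside the cut-point bands so that the
# pipeline's minute classification recovers the generator labels exactly
DEFAULT_COUNTS: dict[int, StateCounts] = {
    SEDENTARY: StateCounts(30.0, 0.8, 1, 99),
    LIGHT: StateCounts(500.0, 0.7, 100, 2019),
    MODERATE: StateCounts(3200.0, 0.35, 2020, 5998),
    VIGOROUS: StateCounts(6800.0, 0.25, 5999, 12000),
}


@dataclass(frozen=True)
class BehaviourProfile:
    """Daily dwell targets and run/count structure for one participant
    (or, with the *_sd fields of SexProfile, a sex-level template)."""

    sex: str
    sleep_min: int
    sedentary_min: float
    light_min: float
    mvpa_min: float
    nonwear_min: float
    vig_frac: float       # share of MVPA minutes that are vigorous
    bout_frac: float      # share of MVPA minutes laid in >=10-min runs
    counts: dict[int, StateCounts] = field(default_factory=lambda: DEFAULT_COUNTS)

    def __post_init__(self) -> None:
        total = (self.sleep_min + self.sedentary_min + self.light_min
                 + self.mvpa_min + self.nonwear_min)
        if abs(total - 1440.0) > 1e-6:
            raise ValueError(f"state minutes sum to {total}, expected 1440")
        if not 0 <= self.vig_frac <= 1 or not 0 <= self.bout_frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class SexProfile:
    """Sex-level behaviour template from which participants are drawn."""

    sex: str
    sleep_min: int = 360
    mvpa_mean: float = 83.0
    mvpa_sd: float = 35.17
    light_mean: float = 128.0
    light_sd: float = 25.0
    sed_mean: float = 541.0
    sed_sd: float = 45.0
    vig_frac_median: float = 0.060
    vig_frac_sigma: float = 0.5
    bout_frac_a: float = 2.0
    bout_frac_b: float = 4.0
    min_nonwear: float = 100.0    # keeps the zero block detectable (>90)


@dataclass
class TrueParticipant:
    """Ground truth for one synthetic participant."""

    id: str
    sex: str                      # 'M' or 'F'
    age_years: float
    height_m: float
    weight_kg: float
    bmi: float
    profile: BehaviourProfile
    true_vo2max: float
    resting_hr: float

    def __post_init__(self) -> None:
        if abs(self.bmi - self.weight_kg / self.height_m ** 2) > 1e-9:
            raise ValueError("bmi inconsistent with weight/height")
        if not 15.0 <= self.true_vo2max <= 80.0:
            raise ValueError(f"true_vo2max {self.true_vo2max} outside [15, 80]")


@dataclass(frozen=True)
class Anthropometry:
    height_mean: float
    height_sd: float
    weight_mean: float
    weight_sd: float


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; defaults are the calibrated cohort."""

    n_male: int = 137
    n_female: int = 119
    n_days: int = 7
    seed: int = 1234
    start_date: Date = Date(2010, 1, 4)

    male_anthro: Anthropometry = Anthropometry(1.72, 0.075, 62.5, 10.2)
    female_anthro: Anthropometry = Anthropometry(1.60, 0.0705, 61.3, 13.4)
    age_low: int = 19
    age_high: int = 20
    resting_hr_mean: float = 65.0
    resting_hr_sd: float = 8.0

    # VO2max generative linear model (see module docstring for derivation)
    # beta0 solves male mean 41.9 = beta0 + 0.03*E[MVPA_m] - 0.30*E[BMI_m] + 7.52
    # with E[MVPA_m]=82.7, E[BMI_m]=21.25 from the default male profile;
    # residual_sd^2 = var(linear predictor)*(0.4/0.6) - 0.62, where 25.6 is the
    # Monte-Carlo variance of the linear predictor over the 137/119 mixture and
    # 0.62 the step-test estimation-error variance at the default 3 bpm HR noise
    beta0: float = 38.27
    beta_mvpa: float = 0.03
    beta_bmi: float = -0.30
    beta_male: float = 7.52
    residual_sd: float = 4.05
    vo2_clip: tuple[float, float] = (15.0, 80.0)

    hr_noise_sd: float = 3.0      # bpm, step-test measurement noise

    # bout_frac Beta(2, b): b solved per sex by Monte Carlo so that 40% of
    # males and 20% of females average >= 30 bouted MVPA min/day
    male_profile: SexProfile = SexProfile(
        sex="M", mvpa_mean=83.0, mvpa_sd=35.17, light_mean=128.0,
        sed_mean=541.0, vig_frac_median=0.060, bout_frac_a=2.0, bout_frac_b=3.75)
    female_profile: SexProfile = SexProfile(
        sex="F", mvpa_mean=43.0, mvpa_sd=22.61, light_mean=132.0,
        sed_mean=575.0, vig_frac_median=0.0233, bout_frac_a=2.0, bout_frac_b=2.53)

    def __post_init__(self) -> None:
        if self.n_male + self.n_female < 2:
            raise ValueError("need at least 2 participants")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


def _clipped_normal(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_participant(cfg: CohortConfig, sex: str, rng: np.random.Generator,
                       pid: str | None = None) -> TrueParticipant:
    """Draw anthropometry, behaviour targets and true VO2max for one person."""
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    anthro = cfg.male_anthro if sex == "M" else cfg.female_anthro
    sp = cfg.male_profile if sex == "M" else cfg.female_profile

    height = _clipped_normal(rng, anthro.height_mean, anthro.height_sd, 1.40, 2.00)
    weight = _clipped_normal(rng, anthro.weight_mean, anthro.weight_sd, 35.0, 120.0)
    bmi = weight / height ** 2
    age = float(rng.integers(cfg.age_low, cfg.age_high + 1))
    resting_hr = _clipped_normal(rng, cfg.resting_hr_mean, cfg.resting_hr_sd, 45.0, 95.0)

    waking = 1440 - sp.sleep_min
    mvpa = max(rng.normal(sp.mvpa_mean, sp.mvpa_sd), 2.0)
    light = max(rng.normal(sp.light_mean, sp.light_sd), 10.0)
    sed = max(rng.normal(sp.sed_mean, sp.sed_sd), 60.0)
    nonwear = waking - sed - light - mvpa
    if nonwear < sp.min_nonwear:          # rare: squeeze sedentary to fit
        sed = max(waking - sp.min_nonwear - light - mvpa, 0.0)
        nonwear = waking - sed - light - mvpa

    vig_frac = float(np.clip(
        math.exp(rng.normal(math.log(sp.vig_frac_median), sp.vig_frac_sigma)),
        0.0, 0.5))
    bout_frac = float(rng.beta(sp.bout_frac_a, sp.bout_frac_b))

    profile = BehaviourProfile(
        sex=sex, sleep_min=sp.sleep_min, sedentary_min=sed, light_min=light,
        mvpa_min=mvpa, nonwear_min=nonwear, vig_frac=vig_frac,
        bout_frac=bout_frac)

    vo2 = (cfg.beta0 + cfg.beta_mvpa * mvpa + cfg.beta_bmi * bmi
           + cfg.beta_male * (sex == "M") + rng.normal(0.0, cfg.residual_sd))
    vo2 = float(np.clip(vo2, *cfg.vo2_clip))

    return TrueParticipant(
        id=pid or "P0000", sex=sex, age_years=age, height_m=height,
        weight_kg=weight, bmi=bmi, profile=profile, true_vo2max=vo2,
        resting_hr=resting_hr)


def _chunk(total: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` minutes into run lengths uniform on [lo, hi]."""
    out: list[int] = []
    rem = int(total)
    while rem > 0:
        ln = min(rem, int(rng.integers(lo, hi + 1)))
        out.append(ln)
        rem -= ln
    return out


def _chunk_bouts(total: int, rng: np.random.Generator,
                 min_len: int = 10, max_len: int = 25) -> tuple[list[int], int]:
    """Split into runs of >= min_len; return (runs, leftover < min_len)."""
    out: list[int] = []
    rem = int(total)
    while rem >= min_len:
        ln = int(rng.integers(min_len, max_len + 1))
        if rem - ln < min_len:
            ln = rem if rem <= max_len + min_len else rem - min_len
        out.append(ln)
        rem -= ln
    return out, rem


def simulate_day_states(profile: BehaviourProfile, rng: np.random.Generator
                        ) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """One day of 1440 per-minute state labels plus run-length ground truth.

    Day budgets vary around the profile targets with Poisson noise, so the
    expected minutes per state equal the targets.  Returns (labels, runs)
    with runs as (state, start, length) in order.
    """
    sleep_n = int(round(profile.sleep_min))
    waking = 1440 - sleep_n
    if waking <= 0:
        labels = np.full(1440, SLEEP, dtype=np.int8)
        return labels, [(SLEEP, 0, 1440)]

    mvpa = int(rng.poisson(profile.mvpa_min))
    light = int(rng.poisson(profile.light_min))
    nonwear = int(rng.poisson(profile.nonwear_min)) if profile.nonwear_min > 0 else 0
    # clamp into the waking budget, preferring to shrink non-wear then light
    over = mvpa + light + nonwear - waking
    if over > 0:
        cut = min(over, nonwear); nonwear -= cut; over -= cut
        cut = min(over, light); light -= cut; over -= cut
        mvpa -= over
    sed = waking - mvpa - light - nonwear

    vig = int(round(profile.vig_frac * mvpa))
    bouted = min(int(round(profile.bout_frac * mvpa)), mvpa - vig)
    bout_runs, leftover = _chunk_bouts(bouted, rng)
    sporadic = mvpa - vig - sum(bout_runs)

    activity: list[tuple[int, int]] = []       # (state, length)
    activity += [(MODERATE, ln) for ln in bout_runs]
    activity += [(MODERATE, ln) for ln in _chunk(sporadic, 1, 6, rng)]
    activity += [(VIGOROUS, ln) for ln in _chunk(vig, 1, 4, rng)]
    order = rng.permutation(len(activity))
    activity = [activity[i] for i in order]

    anchors: list[tuple[int, int]] = []
    anchors += [(SEDENTARY, ln) for ln in _chunk(sed, 10, 40, rng)]
    anchors += [(LIGHT, ln) for ln in _chunk(light, 3, 15, rng)]
    # ensure enough gaps to separate every activity run (avoids accidental
    # merging of short MVPA runs into >=10-min bouts)
    while len(anchors) + 1 < len(activity):
        i = max(range(len(anchors)), key=lambda j: anchors[j][1], default=-1)
        if i < 0 or anchors[i][1] < 2:
            break
        state, ln = anchors[i]
        half = ln // 2
        anchors[i] = (state, half)
        anchors.append((state, ln - half))
    if nonwear > 0:
        anchors.append((NONWEAR, nonwear))
    aorder = rng.permutation(len(anchors))
    anchors = [anchors[i] for i in aorder]

    runs: list[tuple[int, int]] = []
    n_gaps = len(anchors) + 1
    if len(activity) <= n_gaps and n_gaps > 0:
        gap_ids = rng.choice(n_gaps, size=len(activity), replace=False)
        by_gap: dict[int, tuple[int, int]] = {int(g): a
                                              for g, a in zip(gap_ids, activity)}
        for i in range(n_gaps):
            if i in by_gap:
                runs.append(by_gap[i])
            if i < len(anchors):
                runs.append(anchors[i])
    else:                                      # degenerate day: accept adjacency
        runs = anchors + activity
        order = rng.permutation(len(runs))
        runs = [runs[i] for i in order]

    seq = [(SLEEP, sleep_n)] + [(s, ln) for s, ln in runs if ln > 0]
    labels = np.repeat([s for s, _ in seq], [ln for _, ln in seq]).astype(np.int8)
    if labels.size != 1440:
        raise AssertionError(f"day assembled {labels.size} minutes")

    run_truth: list[tuple[int, int, int]] = []
    pos = 0
    for s, ln in seq:
        run_truth.append((int(s), pos, int(ln)))
        pos += ln
    return labels, run_truth


def _truncated_lognormal(rng: np.random.Generator, n: int,
                         sc: StateCounts) -> np.ndarray:
    """Integer counts in [lo, hi] from a lognormal truncated to the band."""
    mu = math.log(sc.median_cpm)
    a = ndtr((math.log(sc.lo) - mu) / sc.sigma)
    b = ndtr((math.log(sc.hi + 1) - mu) / sc.sigma)
    u = rng.uniform(a, b, size=n)
    x = np.exp(mu + sc.sigma * ndtri(u))
    return np.clip(np.floor(x), sc.lo, sc.hi).astype(np.int64)


def states_to_counts(labels: np.ndarray, profile: BehaviourProfile,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-minute labels -> 5-s counts (12 per minute), flattened.

    Sleep/non-wear minutes are all-zero; active minutes draw a 60-s count
    truncated to the labelled band and split it multinomially over the
    twelve 5-s epochs, so reintegration recovers the minute count exactly.
    """
    labels = np.asarray(labels)
    n = labels.size
    minute_counts = np.zeros(n, dtype=np.int64)
    for state, sc in profile.counts.items():
        mask = labels == state
        k = int(mask.sum())
        if k:
            minute_counts[mask] = _truncated_lognormal(rng, k, sc)
    epochs = rng.multinomial(minute_counts, np.full(12, 1 / 12))
    return epochs.reshape(-1).astype(np.int64)


def simulate_participant_week(p: TrueParticipant, n_days: int,
                              rng: np.random.Generator
                              ) -> tuple[np.ndarray, np.ndarray]:
    """(labels (n_days, 1440), 5-s counts (n_days, 17280)) for one person."""
    labels = np.empty((n_days, 1440), dtype=np.int8)
    for d in range(n_days):
        labels[d], _ = simulate_day_states(p.profile, rng)
    counts = states_to_counts(labels.reshape(-1), p.profile, rng)
    return labels, counts.reshape(n_days, 17280)


def simulate_step_test(p: TrueParticipant, cfg: RunConfig,
                       hr_noise_sd: float, rng: np.random.Generator
                       ) -> StepTestRecord:
    """Simulate the 15-s HR trace of one ramped step test.

    HR rises linearly with predicted workload between resting HR (at the
    resting oxygen cost of 3.5 mlO2/kg/min) and the age-predicted maximal
    HR (at the true VO2max), plus Gaussian noise; recovery decays
    exponentially toward resting over the 2-min seated period.
    """
    if p.true_vo2max <= RESTING_VO2:
        raise ValueError(f"true_vo2max {p.true_vo2max} must exceed {RESTING_VO2}")
    proto = cfg.protocol
    width = proto.hr_summary_interval_s
    n_ramp = int(proto.ramp_duration_s / width)
    n_rec = int(proto.recovery_duration_s / width)
    ramp_mids = (np.arange(n_ramp) + 0.5) * width
    rec_mids = proto.ramp_duration_s + (np.arange(n_rec) + 0.5) * width

    max_hr = predict_max_hr(p.age_years, cfg)
    k = (max_hr - p.resting_hr) / (p.true_vo2max - RESTING_VO2)
    w = predict_workload_vo2(ramp_mids, proto)
    hr_ramp = p.resting_hr + (np.asarray(w) - RESTING_VO2) * k

    hr_end = hr_ramp[-1]
    tau = 40.0                                  # s, recovery time constant
    hr_rec = p.resting_hr + (hr_end - p.resting_hr) * np.exp(
        -(rec_mids - proto.ramp_duration_s) / tau)

    hr = np.concatenate([hr_ramp, hr_rec])
    if hr_noise_sd > 0:
        hr = hr + rng.normal(0.0, hr_noise_sd, size=hr.size)
    hr = np.maximum(hr, 1.0)

    return StepTestRecord(
        participant_id=p.id,
        times_s=np.concatenate([ramp_mids, rec_mids]),
        hr_bpm=hr,
        resting_hr=p.resting_hr,
        age_years=p.age_years,
        mass_kg=p.weight_kg,
        test_end_s=proto.ramp_duration_s,
        true_vo2max=p.true_vo2max,
    )


def sample_cohort(cfg: CohortConfig, rng: np.random.Generator
                  ) -> list[TrueParticipant]:
    """Draw all participants (males first, then females)."""
    people: list[TrueParticipant] = []
    k = 0
    for sex, n in (("M", cfg.n_male), ("F", cfg.n_female)):
        for _ in range(n):
            k += 1
            people.append(sample_participant(cfg, sex, rng, pid=f"P{k:04d}"))
    return people


def iter_cohort_data(cfg: CohortConfig, run_cfg: RunConfig | None = None,
                     rng: np.random.Generator | None = None
                     ) -> Iterator[tuple[TrueParticipant, np.ndarray,
                                         np.ndarray, StepTestRecord]]:
    """Yield (participant, day labels, 5-s counts, step test) per person."""
    run_cfg = run_cfg or RunConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    for p in sample_cohort(cfg, rng):
        labels, counts = simulate_participant_week(p, cfg.n_days, rng)
        rec = simulate_step_test(p, run_cfg, cfg.hr_noise_sd, rng)
        yield p, labels, counts, rec


def truth_frame(people: list[TrueParticipant]) -> pd.DataFrame:
    rows = []
    for p in people:
        pr = p.profile
        rows.append({
            "id": p.id, "sex": p.sex, "age_years": p.age_years,
            "height_m": p.height_m, "weight_kg": p.weight_kg, "bmi": p.bmi,
            "true_sleep_min": pr.sleep_min, "true_sedentary_min": pr.sedentary_min,
            "true_light_min": pr.light_min, "true_mvpa_min": pr.mvpa_min,
            "true_nonwear_min": pr.nonwear_min, "true_vig_frac": pr.vig_frac,
            "true_bout_frac": pr.bout_frac, "true_vo2max": p.true_vo2max,
            "resting_hr": p.resting_hr,
        })
    return pd.DataFrame(rows)


def generate_cohort(cfg: CohortConfig, outdir: str | Path,
                    run_cfg: RunConfig | None = None) -> pd.DataFrame:
    """Write the full synthetic cohort to disk; return the ground truth.

    Layout: ``counts/<id>_day<k>.csv`` (one 5-s count file per
    participant-day), ``steptests/<id>.csv``, ``anthropometry.csv``,
    ``ground_truth.csv`` and ``generator_model.csv`` (the linear-model
    coefficients used).  Fully reproducible from cfg.seed.
    """
    outdir = Path(outdir)
    (outdir / "counts").mkdir(parents=True, exist_ok=True)
    (outdir / "steptests").mkdir(parents=True, exist_ok=True)

    people: list[TrueParticipant] = []
    for p, labels, counts, rec in iter_cohort_data(cfg, run_cfg):
        people.append(p)
        for d in range(cfg.n_days):
            day = cfg.start_date + timedelta(days=d)
            cf = CountFile(
                participant_id=p.id,
                start_time=datetime.combine(day, datetime.min.time()),
                epoch_seconds=5,
                counts=counts[d],
            )
            write_count_file(cf, outdir / "counts" / f"{p.id}_day{d + 1}.csv")
        write_step_test(rec, outdir / "steptests" / f"{p.id}.csv")

    truth = truth_frame(people)
    anthro = truth[["id", "sex", "age_years", "height_m", "weight_kg"]]
    anthro.to_csv(outdir / "anthropometry.csv", index=False)
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    pd.DataFrame([{
        "beta0": cfg.beta0, "beta_mvpa": cfg.beta_mvpa,
        "beta_bmi": cfg.beta_bmi, "beta_male": cfg.beta_male,
        "residual_sd": cfg.residual_sd, "hr_noise_sd": cfg.hr_noise_sd,
        "seed": cfg.seed,
    }]).to_csv(outdir / "generator_model.csv", index=False)
    return truth
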