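"""Submaximal ramped step-test VO2max estimation.

The participant steps at a linearly increasing cadence on a fixed-height
step.  Predicted oxygen cost at each moment follows the ACSM stepping
equation; heart rate above resting is regressed on predicted workload over
15-s bins, and the line is extrapolated to the age-predicted maximal heart
rate (Tanaka, 208 - 0.7*age) to estimate VO2max in mlO2/kg/min.

Because workload is expressed as gross oxygen cost (it includes the 3.5
mlO2/kg/min resting term), the extrapolated workload at maximal HR is the
VO2max estimate directly:

    vo2max = (maxHR - restingHR - intercept) / slope

Recovery heart rate (drop over the first 60 s of seated recovery) is
computed as a diagnostic; its weight in the estimate defaults to zero
because no reproducible combination formula is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import RunConfig, StepProtocol
from .io import StepTestRecord


class UnphysiologicalResponseError(ValueError):
    """HR did not rise with workload; no extrapolation is possible."""


@dataclass
class FitnessEstimate:
    """Estimated VO2max with regression diagnostics and quality flags."""

    participant_id: str
    vo2max: float                 # mlO2/kg/min
    slope: float                  # bpm per mlO2/kg/min
    intercept: float              # bpm
    r2_fit: float
    n_points_used: int
    hr_recovery_60s: float        # bpm drop over first 60 s of recovery
    short_test: bool
    poor_fit: bool
    clipped: bool


def cadence_at(t: float | np.ndarray, protocol: StepProtocol) -> np.ndarray:
    """Cadence (steps/min) at time t of the linear ramp."""
    frac = np.asarray(t, dtype=float) / protocol.ramp_duration_s
    return protocol.cadence_start + frac * (protocol.cadence_end - protocol.cadence_start)


def predict_workload_vo2(t: float | np.ndarray,
                         protocol: StepProtocol) -> float | np.ndarray:
    """Predicted gross oxygen cost (mlO2/kg/min) at ramp time t.

    ACSM stepping equation: 0.2*f + 1.33*1.8*h*f + 3.5, with f the cadence
    in steps/min and h the step height in metres.
    """
    t_arr = np.asarray(t, dtype=float)
    if (t_arr < 0).any() or (t_arr > protocol.ramp_duration_s).any():
        raise ValueError("t outside the ramp")
    f = cadence_at(t_arr, protocol)
    vo2 = 0.2 * f + 1.33 * 1.8 * protocol.step_height_m * f + 3.5
    return float(vo2) if np.isscalar(t) or np.ndim(t) == 0 else vo2


def summarise_hr(times_s: np.ndarray, hr_bpm: np.ndarray,
                 cfg: RunConfig | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average raw HR samples into 15-s bins and flag artifacts.

    Returns (bin_midpoints_s, bin_means_bpm, artifact_mask).  A bin is
    flagged if its mean lies outside the plausible HR range or jumps more
    than the configured limit from the previous unflagged bin - a
    deterministic stand-in for visual review of the ECG.
    """
    cfg = cfg or RunConfig()
    times_s = np.asarray(times_s, dtype=float)
    hr_bpm = np.asarray(hr_bpm, dtype=float)
    if times_s.size < 1:
        raise ValueError("no HR samples")
    width = cfg.protocol.hr_summary_interval_s
    idx = np.floor(times_s / width).astype(int)
    n_bins = int(idx.max()) + 1
    sums = np.bincount(idx, weights=hr_bpm, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    mids = (np.arange(n_bins) + 0.5) * width

    lo, hi = cfg.hr_range_bpm
    mask = np.isnan(means) | (means < lo) | (means > hi)
    prev = None
    for k in range(n_bins):
        if mask[k]:
            continue
        if prev is not None and abs(means[k] - means[prev]) > cfg.hr_artifact_jump_bpm:
            mask[k] = True
            continue
        prev = k
    if mask.all():
        raise ValueError("no usable HR: every bin masked")
    return mids, means, mask


def check_test_validity(rec: StepTestRecord, cfg: RunConfig | None = None) -> bool:
    """A test is usable if it lasted >=4 min and has enough clean ramp bins."""
    cfg = cfg or RunConfig()
    if rec.test_end_s < cfg.min_test_seconds:
        return False
    mids, means, mask = summarise_hr(rec.times_s, rec.hr_bpm, cfg)
    on_ramp = mids <= rec.test_end_s
    return int((on_ramp & ~mask).sum()) >= cfg.min_ramp_bins


def fit_hr_response(rec: StepTestRecord, cfg: RunConfig | None = None
                    ) -> tuple[float, float, float, int]:
    """OLS of (HR - resting) on predicted workload over clean ramp bins.

    Returns (slope bpm per mlO2/kg/min, intercept bpm, r^2, n_points).
    """
    cfg = cfg or RunConfig()
    protocol = cfg.protocol
    mids, means, mask = summarise_hr(rec.times_s, rec.hr_bpm, cfg)
    keep = (mids <= min(rec.test_end_s, protocol.ramp_duration_s)) & ~mask
    x = predict_workload_vo2(mids[keep], protocol)
    y = means[keep] - rec.resting_hr
    if np.unique(x).size < 2:
        raise ValueError("fewer than 2 distinct workload values")
    res = sps.linregress(x, y)
    if res.slope <= 0:
        raise UnphysiologicalResponseError(
            f"non-positive HR/workload slope {res.slope:.3g}")
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2), int(x.size)


def predict_max_hr(age_years: float, cfg: RunConfig | None = None) -> float:
    """Age-predicted maximal heart rate, 208 - 0.7*age by default."""
    cfg = cfg or RunConfig()
    if not 5 <= age_years <= 100:
        raise ValueError(f"age {age_years} outside supported range")
    return cfg.max_hr_intercept - cfg.max_hr_slope * age_years


def hr_recovery_60s(rec: StepTestRecord, cfg: RunConfig | None = None) -> float:
    """HR drop from test end to 60 s into recovery (bpm), NaN if unavailable."""
    cfg = cfg or RunConfig()
    try:
        mids, means, mask = summarise_hr(rec.times_s, rec.hr_bpm, cfg)
    except ValueError:
        return float("nan")
    width = cfg.protocol.hr_summary_interval_s
    end_bin = np.argmin(np.abs(mids - (rec.test_end_s - width / 2)))
    rec_bin = np.argmin(np.abs(mids - (rec.test_end_s + 60 - width / 2)))
    if mask[end_bin] or mask[rec_bin] or rec_bin == end_bin:
        return float("nan")
    return float(means[end_bin] - means[rec_bin])


def estimate_vo2max(rec: StepTestRecord, cfg: RunConfig | None = None) -> FitnessEstimate:
    """Extrapolate the submaximal HR-workload line to age-predicted max HR."""
    cfg = cfg or RunConfig()
    slope, intercept, r2, n_used = fit_hr_response(rec, cfg)
    max_hr = predict_max_hr(rec.age_years, cfg)
    vo2 = (max_hr - rec.resting_hr - intercept) / slope

    recovery = hr_recovery_60s(rec, cfg)
    if cfg.recovery_weight != 0.0 and np.isfinite(recovery):
        # extension hook: expected recovery taken as the cohort-typical 30 bpm
        vo2 += cfg.recovery_weight * (recovery - 30.0)

    lo, hi = cfg.vo2max_clip
    clipped = not lo <= vo2 <= hi
    vo2 = float(np.clip(vo2, lo, hi))
    return FitnessEstimate(
        participant_id=rec.participant_id,
        vo2max=vo2,
        slope=slope,
        intercept=intercept,
        r2_fit=r2,
        n_points_used=n_used,
        hr_recovery_60s=recovery,
        short_test=rec.test_end_s < cfg.protocol.ramp_duration_s,
        poor_fit=r2 < 0.5,
        clipped=clipped,
    )


def classify_fitness(vo2max: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Sex-specific median split: 'fit' at or above the sex median.

    Sexes with fewer than 2 participants are left unlabelled ('') with a
    warning.
    """
    import warnings

    vo2max = np.asarray(vo2max, dtype=float)
    sex = np.asarray(sex)
    labels = np.full(vo2max.shape, "", dtype=object)
    for s in np.unique(sex):
        idx = sex == s
        if idx.sum() < 2:
            warnings.warn(f"sex group {s!r} has <2 participants; left unlabelled",
                          stacklevel=2)
            continue
        med = np.median(vo2max[idx])
        labels[idx] = np.where(vo2max[idx] >= med, "fit", "unfit")
    return labels
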