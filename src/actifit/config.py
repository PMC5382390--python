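"""Run configuration: cut-points, wear rules, protocol and statistics options.

All thresholds that drive the pipeline live here as named keys so that
sensitivity analyses need no code change.  The defaults implement the
conventional GT1M uniaxial analysis: Troiano-style intensity cut-points
(light from 100 cpm, moderate from 2020 cpm, vigorous from 5999 cpm),
non-wear as a run of more than 90 consecutive zero-count minutes, a
500-min wear requirement per valid day, at least 3 valid days per
participant, strict 10-min MVPA bouts, the CDC (150 min MVPA or 75 min
vigorous per week, prorated daily) and WHO (30 min/day of bouted MVPA)
guideline rules, and a 20-cm ramped step test.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any


@dataclass(frozen=True)
class StepProtocol:
    """Ramped step-test protocol.

    A fixed-height step with a linearly increasing cadence prompt, followed
    by seated recovery.  Heart rate is summarised in fixed intervals.
    """

    step_height_m: float = 0.20
    ramp_duration_s: float = 480.0
    recovery_duration_s: float = 120.0
    cadence_start: float = 15.0   # steps/min at ramp start
    cadence_end: float = 33.0     # steps/min at ramp end
    hr_summary_interval_s: float = 15.0

    def __post_init__(self) -> None:
        if self.step_height_m <= 0:
            raise ValueError("step_height_m must be positive")
        if self.ramp_duration_s <= 0:
            raise ValueError("ramp_duration_s must be positive")
        if self.cadence_end <= self.cadence_start:
            raise ValueError("cadence_end must exceed cadence_start")
        if self.hr_summary_interval_s <= 0:
            raise ValueError("hr_summary_interval_s must be positive")


@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of the processing and analysis pipeline."""

    # intensity cut-points on integer counts per minute: bands are
    # [0, light_min), [light_min, moderate_min), [moderate_min, vigorous_min),
    # [vigorous_min, inf)
    light_min: int = 100
    moderate_min: int = 2020
    vigorous_min: int = 5999

    # non-wear: a run of strictly more than this many consecutive
    # zero-count minutes is flagged as non-wear
    nonwear_min_zero_minutes: int = 90

    # clock-time window removed as sleep, half-open [start, end)
    sleep_window: tuple[str, str] = ("00:00", "06:00")

    # day/participant validity
    min_wear_minutes_per_day: int = 500
    min_valid_days: int = 3
    # whether the 500-min wear requirement counts sleep-window minutes
    wear_requirement_after_sleep_removal: bool = True

    # bouts and guideline rules
    bout_min_minutes: int = 10
    cdc_weekly_mvpa_min: float = 150.0
    cdc_weekly_vigorous_min: float = 75.0
    who_daily_bouted_mvpa_min: float = 30.0

    # step test
    protocol: StepProtocol = field(default_factory=StepProtocol)
    max_hr_intercept: float = 208.0   # age-predicted max HR = intercept - slope*age
    max_hr_slope: float = 0.7
    hr_artifact_jump_bpm: float = 30.0
    hr_range_bpm: tuple[float, float] = (30.0, 220.0)
    min_test_seconds: float = 240.0
    min_ramp_bins: int = 6
    recovery_weight: float = 0.0      # weight of the recovery-HR adjustment
    vo2max_clip: tuple[float, float] = (10.0, 90.0)

    # statistics
    alpha: float = 0.05
    bootstrap_reps: int = 2000
    collinearity_r_max: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.light_min < self.moderate_min < self.vigorous_min):
            raise ValueError(
                "cut-points must satisfy 0 < light_min < moderate_min < vigorous_min"
            )
        if self.nonwear_min_zero_minutes < 1:
            raise ValueError("nonwear_min_zero_minutes must be >= 1")
        if self.min_wear_minutes_per_day < 1:
            raise ValueError("min_wear_minutes_per_day must be >= 1")
        if self.min_valid_days < 1:
            raise ValueError("min_valid_days must be >= 1")
        if self.bout_min_minutes < 1:
            raise ValueError("bout_min_minutes must be >= 1")
        for name in ("cdc_weekly_mvpa_min", "cdc_weekly_vigorous_min",
                     "who_daily_bouted_mvpa_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for t in self.sleep_window:
            _parse_clock(t)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


def _parse_clock(text: str) -> int:
    """'HH:MM' -> minute of day in [0, 1440]."""
    try:
        hh, mm = text.split(":")
        h, m = int(hh), int(mm)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"bad clock time {text!r}, expected HH:MM") from exc
    if not (0 <= h <= 24 and 0 <= m < 60) or (h == 24 and m != 0):
        raise ValueError(f"clock time {text!r} out of range")
    return h * 60 + m


def sleep_window_minutes(cfg: RunConfig) -> tuple[int, int]:
    """Sleep window as half-open [start, end) minutes of day."""
    return _parse_clock(cfg.sleep_window[0]), _parse_clock(cfg.sleep_window[1])


_PROTOCOL_KEYS = {f.name for f in fields(StepProtocol)}
_CONFIG_KEYS = {f.name for f in fields(RunConfig)}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a RunConfig from a flat TOML key-value file.

    Missing keys fall back to the defaults above; calling with no path
    returns the pure defaults.  Unknown keys raise a warning, mistyped
    values an error.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        raw: dict[str, Any] = tomllib.load(fh)

    cfg_updates: dict[str, Any] = {}
    proto_updates: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _PROTOCOL_KEYS:
            proto_updates[key] = value
        elif key in _CONFIG_KEYS:
            if key in ("sleep_window", "hr_range_bpm", "vo2max_clip"):
                value = tuple(value)
            cfg_updates[key] = value
        else:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)

    for key, value in cfg_updates.items():
        expected = type(getattr(cfg, key))
        if expected in (int, float) and not isinstance(value, bool) and \
                isinstance(value, (int, float)):
            continue
        if not isinstance(value, expected):
            raise TypeError(
                f"config key {key!r}: expected {expected.__name__}, "
                f"got {type(value).__name__}"
            )
    if proto_updates:
        cfg_updates["protocol"] = replace(StepProtocol(), **proto_updates)
    return replace(cfg, **cfg_updates)
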