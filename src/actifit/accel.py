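"""Accelerometer count processing: epochs to guideline classifications.

The stages, in order: reintegrate 5-s epochs to counts per minute (cpm),
flag non-wear (runs of more than 90 consecutive zero minutes), remove the
overnight sleep window, apply intensity cut-points on integer cpm, tally
per-day minutes, detect strict consecutive-minute MVPA bouts, screen day
(>=500 wear min) and participant (>=3 valid days) validity, and classify
adherence to the CDC (prorated weekly total) and WHO (daily bouted)
physical-activity recommendations.

Conventions adopted where the source rules are ambiguous:

* the sleep window "12 pm and 6 am" is taken as midnight-06:00 half-open
  (removing noon-to-6am would discard most of the waking day);
* non-wear is detected on the full minute stream BEFORE sleep removal, so
  a sleep-window zero run can extend a non-wear run;
* "continuous" zeros and "consecutive" bout minutes are strict - any
  interruption breaks the run, and bouts never bridge sleep or non-wear;
* wear-time validity is evaluated after sleep removal (config-switchable).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date, datetime, timedelta

import numpy as np

from .config import RunConfig, sleep_window_minutes
from .io import CountFile

# intensity codes; NONWEAR/SLEEP only appear in generator ground truth
SEDENTARY, LIGHT, MODERATE, VIGOROUS = 0, 1, 2, 3
INTENSITY_NAMES = {SEDENTARY: "sedentary", LIGHT: "light",
                   MODERATE: "moderate", VIGOROUS: "vigorous"}


@dataclass
class MinuteSeries:
    """One calendar day of minute-level counts with wear and sleep masks.

    ``cpm`` has 1440 slots aligned to the local clock; NaN marks minutes
    the recording does not cover.
    """

    participant_id: str
    date: Date
    cpm: np.ndarray               # float, NaN = not recorded
    wear: np.ndarray              # bool, False where non-wear or unrecorded
    sleep: np.ndarray             # bool, True inside the sleep window

    def __post_init__(self) -> None:
        for name in ("cpm", "wear", "sleep"):
            arr = getattr(self, name)
            if arr.shape != (1440,):
                raise ValueError(f"{name} must have 1440 slots, got {arr.shape}")
        observed = ~np.isnan(self.cpm)
        if (self.cpm[observed] < 0).any():
            raise ValueError("negative cpm")


@dataclass
class DaySummary:
    """Per-day wear minutes, minutes by intensity band, and bouted MVPA."""

    date: Date
    wear_min: int
    sedentary_min: int
    light_min: int
    moderate_min: int
    vigorous_min: int
    mvpa_min: int
    bouted_mvpa_min: int
    bouted_vigorous_min: int
    n_mvpa_bouts: int
    mean_cpm: float
    valid: bool


@dataclass
class ParticipantActivity:
    """Across-valid-days averages and guideline classifications."""

    participant_id: str
    n_days: int
    n_valid_days: int
    valid: bool
    wear_min: float
    sedentary_min: float
    light_min: float
    moderate_min: float
    vigorous_min: float
    mvpa_min: float
    bouted_mvpa_min: float
    bouted_vigorous_min: float
    mean_cpm: float
    active_cdc: bool | None
    active_who: bool | None


def integrate_epochs(cf: CountFile) -> CountFile:
    """Reintegrate a 5-s count stream to 60-s epochs (counts per minute).

    The stream is first snapped forward to the next whole clock minute;
    a trailing partial minute is dropped.  Each output count is the sum of
    twelve consecutive 5-s counts, so totals are conserved up to the
    dropped head/tail.
    """
    if cf.epoch_seconds != 5:
        raise ValueError(f"expected 5-s epochs, got {cf.epoch_seconds}")
    offset_s = cf.start_time.second + 60 * 0 + cf.start_time.microsecond / 1e6
    if offset_s % 5 != 0:
        raise ValueError("start time not aligned to the 5-s epoch grid")
    skip = int(((60 - offset_s) % 60) // 5)
    counts = cf.counts[skip:]
    n_min = counts.size // 12
    if n_min == 0:
        raise ValueError("stream shorter than one whole minute after alignment")
    cpm = counts[: n_min * 12].reshape(n_min, 12).sum(axis=1)
    return CountFile(
        participant_id=cf.participant_id,
        start_time=cf.start_time + timedelta(seconds=skip * 5),
        epoch_seconds=60,
        counts=cpm,
    )


def _bool_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and lengths of maximal True runs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return starts, ends - starts


def detect_nonwear(cpm: np.ndarray, min_zero_run: int = 90) -> np.ndarray:
    """Wear mask over minute counts: False inside long zero runs.

    Minutes inside any maximal run of consecutive zero-count minutes of
    length strictly greater than ``min_zero_run`` are non-wear (the
    conventional ">90 min of continuous zeros" rule).  NaN (unrecorded)
    minutes are non-wear themselves and break zero runs.
    """
    cpm = np.asarray(cpm, dtype=float)
    observed = ~np.isnan(cpm)
    wear = observed.copy()
    zero = observed & (cpm == 0)
    starts, lengths = _bool_runs(zero)
    for s, ln in zip(starts, lengths):
        if ln > min_zero_run:
            wear[s:s + ln] = False
    return wear


def sleep_mask_for_day(cfg: RunConfig) -> np.ndarray:
    """Boolean mask over the 1440 minutes of a day, True inside the window."""
    start, end = sleep_window_minutes(cfg)
    mask = np.zeros(1440, dtype=bool)
    if start == end:
        return mask               # empty window: nothing removed
    if start < end:
        mask[start:end] = True
    else:                         # wraps midnight
        mask[start:] = True
        mask[:end] = True
    return mask


def apply_sleep_window(ms: MinuteSeries, cfg: RunConfig) -> MinuteSeries:
    """Mark minutes whose clock time falls in the configured sleep window."""
    ms.sleep = sleep_mask_for_day(cfg)
    return ms


def classify_intensity(cpm: float, cfg: RunConfig | None = None) -> str:
    """Intensity label for one integer cpm value."""
    cfg = cfg or RunConfig()
    if cpm < 0:
        raise ValueError(f"negative cpm {cpm}")
    return INTENSITY_NAMES[int(intensity_codes(np.asarray([cpm]), cfg)[0])]


def intensity_codes(cpm: np.ndarray, cfg: RunConfig | None = None) -> np.ndarray:
    """Vectorised intensity classification on integer cpm.

    Bands: [0, light_min), [light_min, moderate_min),
    [moderate_min, vigorous_min), [vigorous_min, inf).
    """
    cfg = cfg or RunConfig()
    cpm = np.asarray(cpm)
    codes = np.zeros(cpm.shape, dtype=np.int8)
    codes[cpm >= cfg.light_min] = LIGHT
    codes[cpm >= cfg.moderate_min] = MODERATE
    codes[cpm >= cfg.vigorous_min] = VIGOROUS
    return codes


def detect_bouts(qualifies: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of qualifying minutes with length >= min_len.

    ``qualifies`` must already be False on sleep and non-wear minutes, so
    runs cannot bridge those gaps.  No interruption tolerance.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    starts, lengths = _bool_runs(np.asarray(qualifies, dtype=bool))
    return [(int(s), int(ln)) for s, ln in zip(starts, lengths) if ln >= min_len]


def minute_series_from_count_file(cf: CountFile, cfg: RunConfig) -> list[MinuteSeries]:
    """Reintegrate, detect non-wear on the whole stream, and split by date.

    Non-wear is detected before splitting so zero runs spanning midnight
    are treated as continuous within one recording.
    """
    minute_cf = integrate_epochs(cf) if cf.epoch_seconds == 5 else cf
    wear_stream = detect_nonwear(minute_cf.counts, cfg.nonwear_min_zero_minutes)
    start = minute_cf.start_time
    if start.second or start.microsecond:
        raise ValueError("minute stream must start on a whole minute")
    first_slot = start.hour * 60 + start.minute
    n = minute_cf.counts.size
    sleep = sleep_mask_for_day(cfg)

    out: list[MinuteSeries] = []
    pos = 0
    day0 = start.date()
    slot = first_slot
    day_idx = 0
    while pos < n:
        take = min(1440 - slot, n - pos)
        cpm = np.full(1440, np.nan)
        wear = np.zeros(1440, dtype=bool)
        cpm[slot:slot + take] = minute_cf.counts[pos:pos + take]
        wear[slot:slot + take] = wear_stream[pos:pos + take]
        out.append(MinuteSeries(
            participant_id=minute_cf.participant_id,
            date=day0 + timedelta(days=day_idx),
            cpm=cpm, wear=wear, sleep=sleep.copy(),
        ))
        pos += take
        slot = 0
        day_idx += 1
    return out


def summarise_day(ms: MinuteSeries, cfg: RunConfig) -> DaySummary:
    """Tally one day over wear, non-sleep minutes."""
    observed = ~np.isnan(ms.cpm)
    use = ms.wear & ~ms.sleep & observed
    cpm_used = ms.cpm[use]
    codes = intensity_codes(cpm_used, cfg)
    tallies = {code: int((codes == code).sum())
               for code in (SEDENTARY, LIGHT, MODERATE, VIGOROUS)}
    wear_min = int(use.sum())

    mvpa_qual = use.copy()
    mvpa_qual[use] = cpm_used >= cfg.moderate_min
    vig_qual = use.copy()
    vig_qual[use] = cpm_used >= cfg.vigorous_min
    mvpa_bouts = detect_bouts(mvpa_qual, cfg.bout_min_minutes)
    vig_bouts = detect_bouts(vig_qual, cfg.bout_min_minutes)

    if cfg.wear_requirement_after_sleep_removal:
        wear_for_validity = wear_min
    else:
        wear_for_validity = int((ms.wear & observed).sum())

    return DaySummary(
        date=ms.date,
        wear_min=wear_min,
        sedentary_min=tallies[SEDENTARY],
        light_min=tallies[LIGHT],
        moderate_min=tallies[MODERATE],
        vigorous_min=tallies[VIGOROUS],
        mvpa_min=tallies[MODERATE] + tallies[VIGOROUS],
        bouted_mvpa_min=sum(ln for _, ln in mvpa_bouts),
        bouted_vigorous_min=sum(ln for _, ln in vig_bouts),
        n_mvpa_bouts=len(mvpa_bouts),
        mean_cpm=float(cpm_used.mean()) if wear_min else float("nan"),
        valid=wear_for_validity >= cfg.min_wear_minutes_per_day,
    )


def classify_cdc(pa: ParticipantActivity, cfg: RunConfig) -> bool:
    """Active if prorated daily MVPA or vigorous time meets the weekly CDC
    recommendation (150 min MVPA and/or 75 min vigorous per week), bouts
    not required."""
    if not pa.valid:
        raise ValueError(f"participant {pa.participant_id} has insufficient valid days")
    return (pa.mvpa_min >= cfg.cdc_weekly_mvpa_min / 7.0
            or pa.vigorous_min >= cfg.cdc_weekly_vigorous_min / 7.0)


def classify_who(pa: ParticipantActivity, cfg: RunConfig) -> bool:
    """Active if average daily MVPA accumulated in >=10-min bouts reaches
    30 min."""
    if not pa.valid:
        raise ValueError(f"participant {pa.participant_id} has insufficient valid days")
    return pa.bouted_mvpa_min >= cfg.who_daily_bouted_mvpa_min


_MEAN_FIELDS = ("wear_min", "sedentary_min", "light_min", "moderate_min",
                "vigorous_min", "mvpa_min", "bouted_mvpa_min",
                "bouted_vigorous_min", "mean_cpm")


def summarise_participant(participant_id: str, days: list[DaySummary],
                          cfg: RunConfig) -> ParticipantActivity:
    """Average valid days and classify guideline adherence."""
    valid_days = [d for d in days if d.valid]
    valid = len(valid_days) >= cfg.min_valid_days
    means = {f: float("nan") for f in _MEAN_FIELDS}
    if valid_days:
        for f in _MEAN_FIELDS:
            means[f] = float(np.mean([getattr(d, f) for d in valid_days]))
    pa = ParticipantActivity(
        participant_id=participant_id,
        n_days=len(days),
        n_valid_days=len(valid_days),
        valid=valid,
        active_cdc=None, active_who=None,
        **means,
    )
    if valid:
        pa.active_cdc = classify_cdc(pa, cfg)
        pa.active_who = classify_who(pa, cfg)
    return pa


def process_participant(count_files: list[CountFile],
                        cfg: RunConfig) -> tuple[ParticipantActivity, list[DaySummary]]:
    """Full per-participant pipeline from raw count streams."""
    if not count_files:
        raise ValueError("no count files")
    pid = count_files[0].participant_id
    days: list[DaySummary] = []
    for cf in count_files:
        if cf.participant_id != pid:
            raise ValueError("count files from different participants")
        for ms in minute_series_from_count_file(cf, cfg):
            days.append(summarise_day(ms, cfg))
    days.sort(key=lambda d: d.date)
    return summarise_participant(pid, days, cfg), days


def process_cpm_matrix(participant_id: str, cpm_days: np.ndarray, start_date: Date,
                       cfg: RunConfig) -> tuple[ParticipantActivity, list[DaySummary]]:
    """Fast path: process an (n_days, 1440) midnight-aligned cpm matrix.

    Equivalent to building one CountFile per day and running
    process_participant; used by the synthetic cohort driver where counts
    are already minute-aligned in memory.
    """
    sleep = sleep_mask_for_day(cfg)
    days = []
    for i in range(cpm_days.shape[0]):
        cpm = np.asarray(cpm_days[i], dtype=float)
        wear = detect_nonwear(cpm, cfg.nonwear_min_zero_minutes)
        ms = MinuteSeries(participant_id=participant_id,
                          date=start_date + timedelta(days=i),
                          cpm=cpm, wear=wear, sleep=sleep.copy())
        days.append(summarise_day(ms, cfg))
    return summarise_participant(participant_id, days, cfg), days
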