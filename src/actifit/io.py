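"""File formats: count streams, step-test traces and cohort tables.

The count format is a minimal self-describing CSV: three header lines
(participant id, ISO-8601 start time, epoch length in seconds) followed by
one non-negative integer count per line.  It round-trips bit-identically,
which the vendor binary dialects do not, and is the only on-disk shape the
rest of the package consumes.

Step-test traces are CSVs with key,value header lines (id, resting_hr,
age_years, mass_kg, test_end_seconds) followed by a ``t_seconds,
heart_rate_bpm`` table.  Cohort anthropometry is a plain CSV with columns
``id,sex,age_years,height_m,weight_kg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


@dataclass
class CountFile:
    """An epoch-level activity-count stream for one participant recording."""

    participant_id: str
    start_time: datetime          # naive local clock time
    epoch_seconds: int            # 5 (raw) or 60 (reintegrated)
    counts: np.ndarray            # 1-D non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.epoch_seconds not in (5, 60):
            raise ValueError(f"epoch_seconds must be 5 or 60, got {self.epoch_seconds}")
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if (self.counts < 0).any():
            bad = int(np.argmax(self.counts < 0))
            raise ValueError(f"negative count at position {bad}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountFile):
            return NotImplemented
        return (self.participant_id == other.participant_id
                and self.start_time == other.start_time
                and self.epoch_seconds == other.epoch_seconds
                and np.array_equal(self.counts, other.counts))


_COUNT_HEADER = ("participant_id", "start_time", "epoch_seconds")


def read_count_file(path: str | Path) -> CountFile:
    """Parse a count CSV, reporting malformed rows with their line numbers."""
    path = Path(path)
    header: dict[str, str] = {}
    counts: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated header (need 3 header lines)")
    for lineno, line in enumerate(lines[:3], start=1):
        try:
            key, value = line.split(",", 1)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
        header[key.strip()] = value.strip()
    missing = [k for k in _COUNT_HEADER if k not in header]
    if missing:
        raise FormatError(f"{path}: missing header fields {missing}")
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        try:
            value = int(line)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: not an integer count: {line!r}")
        if value < 0:
            raise ValueError(f"{path}:{lineno}: negative count {value}")
        counts.append(value)
    if not counts:
        raise FormatError(f"{path}: no count records")
    return CountFile(
        participant_id=header["participant_id"],
        start_time=datetime.fromisoformat(header["start_time"]),
        epoch_seconds=int(header["epoch_seconds"]),
        counts=np.asarray(counts, dtype=np.int64),
    )


def write_count_file(cf: CountFile, path: str | Path) -> None:
    """Write a count CSV that round-trips bit-identically via read_count_file."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"participant_id,{cf.participant_id}\n")
        fh.write(f"start_time,{cf.start_time.isoformat()}\n")
        fh.write(f"epoch_seconds,{cf.epoch_seconds}\n")
        fh.write("\n".join(str(int(c)) for c in cf.counts))
        fh.write("\n")


@dataclass
class StepTestRecord:
    """One submaximal step test: HR trace plus protocol metadata.

    ``times_s``/``hr_bpm`` hold the trace samples (seconds from test start).
    ``true_vo2max`` is carried only by synthetic records for recovery tests.
    """

    participant_id: str
    times_s: np.ndarray
    hr_bpm: np.ndarray
    resting_hr: float
    age_years: float
    mass_kg: float
    test_end_s: float             # actual duration stepped (<= ramp duration)
    artifact_mask: np.ndarray | None = None   # True where sample is unusable
    true_vo2max: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if self.times_s.shape != self.hr_bpm.shape:
            raise ValueError("times_s and hr_bpm must have equal length")
        if self.times_s.size < 1:
            raise ValueError("empty HR trace")
        if not 0 < self.resting_hr < 220:
            raise ValueError(f"implausible resting_hr {self.resting_hr}")
        if (self.hr_bpm <= 0).any():
            raise ValueError("non-positive HR sample")


def read_step_test(path: str | Path) -> StepTestRecord:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    header: dict[str, str] = {}
    body_start = None
    for i, line in enumerate(lines):
        if line.startswith("t_seconds"):
            body_start = i
            break
        key, _, value = line.partition(",")
        header[key.strip()] = value.strip()
    if body_start is None:
        raise FormatError(f"{path}: missing t_seconds,heart_rate_bpm table")
    required = ("id", "resting_hr", "age_years", "mass_kg", "test_end_seconds")
    missing = [k for k in required if k not in header]
    if missing:
        raise FormatError(f"{path}: missing header fields {missing}")
    times, hrs = [], []
    for lineno, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line.strip():
            continue
        try:
            t_str, hr_str = line.split(",")
            times.append(float(t_str))
            hrs.append(float(hr_str))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed trace row {line!r}")
    return StepTestRecord(
        participant_id=header["id"],
        times_s=np.asarray(times),
        hr_bpm=np.asarray(hrs),
        resting_hr=float(header["resting_hr"]),
        age_years=float(header["age_years"]),
        mass_kg=float(header["mass_kg"]),
        test_end_s=float(header["test_end_seconds"]),
    )


def write_step_test(rec: StepTestRecord, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"id,{rec.participant_id}\n")
        fh.write(f"resting_hr,{float(rec.resting_hr)!r}\n")
        fh.write(f"age_years,{float(rec.age_years)!r}\n")
        fh.write(f"mass_kg,{float(rec.mass_kg)!r}\n")
        fh.write(f"test_end_seconds,{float(rec.test_end_s)!r}\n")
        fh.write("t_seconds,heart_rate_bpm\n")
        for t, hr in zip(rec.times_s, rec.hr_bpm):
            fh.write(f"{float(t)!r},{float(hr)!r}\n")


COHORT_COLUMNS = ["id", "sex", "age_years", "height_m", "weight_kg"]


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cohort columns {missing}")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
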