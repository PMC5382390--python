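#!/usr/bin/env python
"""Process raw count files into day and participant activity summaries.

Reads every 5-s count CSV under <cohort>/counts, reintegrates to counts
per minute, removes non-wear (>90 min continuous zeros) and the overnight
sleep window, applies the intensity cut-points, detects strict 10-min
MVPA bouts, screens day (>=500 wear min) and participant (>=3 valid days)
validity, and classifies CDC/WHO guideline adherence.

    python analysis/02_process_accelerometry.py [--cohort scratch/cohort]
        [--out results] [--config run.toml]
"""

import argparse
from collections import defaultdict
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from actifit.accel import process_participant
from actifit.config import load_config
from actifit.io import read_count_file


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--config", type=Path, default=None)
    args = ap.parse_args()
    cfg = load_config(args.config)

    by_participant = defaultdict(list)
    for path in sorted((args.cohort / "counts").glob("*.csv")):
        cf = read_count_file(path)
        by_participant[cf.participant_id].append(cf)

    day_rows, part_rows = [], []
    for pid, files in sorted(by_participant.items()):
        pa, days = process_participant(files, cfg)
        row = asdict(pa)
        row["id"] = row.pop("participant_id")
        part_rows.append(row)
        for d in days:
            dr = asdict(d)
            dr["id"] = pid
            day_rows.append(dr)

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(day_rows).to_csv(args.out / "day_summaries.csv", index=False)
    part = pd.DataFrame(part_rows)
    part.to_csv(args.out / "participant_activity.csv", index=False)

    valid = part[part.valid]
    print(f"{len(part)} participants processed, {len(valid)} valid "
          f"(>= {cfg.min_valid_days} days with >= {cfg.min_wear_minutes_per_day} wear min)")
    print(f"median daily MVPA {valid.mvpa_min.median():.1f} min, "
          f"sedentary {valid.sedentary_min.median():.1f} min, "
          f"bouted MVPA {valid.bouted_mvpa_min.median():.1f} min")
    print(f"active: CDC {100 * valid.active_cdc.mean():.1f}%, "
          f"WHO (bouted) {100 * valid.active_who.mean():.1f}%")


if __name__ == "__main__":
    main()
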