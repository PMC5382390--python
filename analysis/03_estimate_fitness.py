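#!/usr/bin/env python
"""Estimate VO2max from every step-test trace.

Reads the 15-s HR traces under <cohort>/steptests, masks artifacts,
regresses HR above resting on the ACSM stepping workload of the ramp and
extrapolates to the age-predicted maximal heart rate.  Invalid tests
(<4 min or too few clean bins) are reported and skipped.

    python analysis/03_estimate_fitness.py [--cohort scratch/cohort]
        [--out results] [--config run.toml]
"""

import argparse
from pathlib import Path

import pandas as pd

from actifit.config import load_config
from actifit.io import read_step_test
from actifit.pipeline import fitness_row
from actifit.steptest import check_test_validity, estimate_vo2max


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--config", type=Path, default=None)
    args = ap.parse_args()
    cfg = load_config(args.config)

    rows, invalid = [], []
    for path in sorted((args.cohort / "steptests").glob("*.csv")):
        rec = read_step_test(path)
        if not check_test_validity(rec, cfg):
            invalid.append(rec.participant_id)
            continue
        rows.append(fitness_row(estimate_vo2max(rec, cfg)))

    args.out.mkdir(parents=True, exist_ok=True)
    est = pd.DataFrame(rows)
    est.to_csv(args.out / "fitness_estimates.csv", index=False)
    print(f"{len(est)} valid tests estimated, {len(invalid)} invalid/skipped")
    print(f"median estimated VO2max {est.vo2max.median():.1f} mlO2/kg/min "
          f"(range {est.vo2max.min():.1f}-{est.vo2max.max():.1f})")
    print(f"median fit r^2 {est.r2_fit.median():.3f}; "
          f"{int(est.clipped.sum())} estimates clipped")


if __name__ == "__main__":
    main()
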