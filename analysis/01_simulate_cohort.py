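#!/usr/bin/env python
"""Simulate the study inputs: anthropometry, 7-day count streams, step tests.

Writes the full synthetic cohort (default 137 males + 119 females) as
plain-text files: one 5-s count CSV per participant-day, one step-test HR
trace per participant, the anthropometry table and the generator ground
truth.  The count files alone run to ~120 MB for the full cohort, so the
default output directory is scratch/cohort.

    python analysis/01_simulate_cohort.py [--outdir scratch/cohort]
        [--n-male 137 --n-female 119 --seed 1234]
"""

import argparse
from dataclasses import replace
from pathlib import Path

from actifit.synthetic import CohortConfig, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--n-male", type=int, default=None)
    ap.add_argument("--n-female", type=int, default=None)
    ap.add_argument("--seed", type=int, default=None)
    args = ap.parse_args()

    cfg = CohortConfig()
    updates = {k: v for k, v in (("n_male", args.n_male),
                                 ("n_female", args.n_female),
                                 ("seed", args.seed)) if v is not None}
    if updates:
        cfg = replace(cfg, **updates)

    truth = generate_cohort(cfg, args.outdir)
    print(f"wrote {len(truth)} participants "
          f"({(truth.sex == 'M').sum()} M, {(truth.sex == 'F').sum()} F) "
          f"x {cfg.n_days} days to {args.outdir}")
    print(f"true MVPA medians: male "
          f"{truth.loc[truth.sex == 'M', 'true_mvpa_min'].median():.1f}, "
          f"female {truth.loc[truth.sex == 'F', 'true_mvpa_min'].median():.1f} min/day")
    print(f"true VO2max medians: male "
          f"{truth.loc[truth.sex == 'M', 'true_vo2max'].median():.1f}, "
          f"female {truth.loc[truth.sex == 'F', 'true_vo2max'].median():.1f} mlO2/kg/min")


if __name__ == "__main__":
    main()
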