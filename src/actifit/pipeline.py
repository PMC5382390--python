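"""End-to-end drivers: synthetic cohort -> processed tables.

Glue that the analysis scripts, tests and reproduction script share: run
the generator, push every participant through the accelerometry pipeline
and the step-test estimator, and assemble the joined cohort table for the
statistics layer.
"""

from __future__ import annotations

from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from .accel import process_cpm_matrix
from .config import RunConfig
from .io import StepTestRecord
from .steptest import estimate_vo2max
from .stats import build_cohort_table
from .synthetic import CohortConfig, iter_cohort_data, truth_frame


def reintegrate_days(counts_5s: np.ndarray) -> np.ndarray:
    """(n_days, 17280) 5-s counts -> (n_days, 1440) counts per minute."""
    n_days = counts_5s.shape[0]
    return counts_5s.reshape(n_days, 1440, 12).sum(axis=2)


def activity_row(pa) -> dict:
    row = asdict(pa)
    row["id"] = row.pop("participant_id")
    return row


def fitness_row(est) -> dict:
    return {"id": est.participant_id, "vo2max": est.vo2max,
            "slope": est.slope, "intercept": est.intercept,
            "r2_fit": est.r2_fit, "n_points_used": est.n_points_used,
            "hr_recovery_60s": est.hr_recovery_60s,
            "short_test": est.short_test, "poor_fit": est.poor_fit,
            "clipped": est.clipped}


def process_cohort(cfg: CohortConfig | None = None,
                   run_cfg: RunConfig | None = None,
                   seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Generate and fully process a synthetic cohort in memory.

    Returns ``truth`` (generator ground truth), ``activity`` (per-
    participant accelerometry summaries), ``fitness`` (step-test
    estimates) and ``cohort`` (the joined analysis table over valid
    participants).
    """
    cfg = cfg or CohortConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    run_cfg = run_cfg or RunConfig()

    people, act_rows, fit_rows = [], [], []
    for p, labels, counts, rec in iter_cohort_data(cfg, run_cfg):
        people.append(p)
        cpm = reintegrate_days(counts)
        pa, _ = process_cpm_matrix(p.id, cpm, cfg.start_date, run_cfg)
        act_rows.append(activity_row(pa))
        fit_rows.append(fitness_row(estimate_vo2max(rec, run_cfg)))

    truth = truth_frame(people)
    activity = pd.DataFrame(act_rows)
    fitness = pd.DataFrame(fit_rows)
    anthro = truth[["id", "sex", "age_years", "height_m", "weight_kg"]]
    valid_activity = activity[activity["valid"]]
    cohort = build_cohort_table(anthro, valid_activity, fitness)
    return {"truth": truth, "activity": activity, "fitness": fitness,
            "cohort": cohort}


def process_step_tests(records: list[StepTestRecord],
                       run_cfg: RunConfig | None = None) -> pd.DataFrame:
    run_cfg = run_cfg or RunConfig()
    return pd.DataFrame([fitness_row(estimate_vo2max(r, run_cfg))
                         for r in records])
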