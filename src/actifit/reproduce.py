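"""Reproduction experiments: recover the reference cohort statistics.

The cohort this package models has no deposited data, so its printed
numbers are reproduced as parameter-recovery experiments: the packaged
default synthetic cohort is calibrated so that the generator ground truth
equals the reference values, and the measurements below check that the
independently implemented pipeline (epoching -> non-wear -> sleep removal
-> validity -> cut-points -> bouts -> guidelines -> step-test estimation
-> statistics) recovers them.

Cohort-level summary statistics at n=256 carry appreciable sampling noise
(the median of 119 female sedentary values has an SE of ~5 min/day), so
the cohort experiments are Monte-Carlo: the default cohort is replicated
over consecutive seeds and each quantity is reported as the mean over
replicates.  The regression-recovery experiment uses one large cohort
(n=5000) at the same male:female ratio.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import RunConfig
from .pipeline import process_cohort
from .stats import multiple_regression, regression_margins
from .steptest import estimate_vo2max
from .synthetic import CohortConfig, sample_participant, simulate_step_test

REGRESSION_PREDICTORS = ["sedentary_min", "mvpa_min", "bmi", "sex"]


def cohort_run_metrics(seed: int) -> dict[str, float]:
    """Process one default cohort end to end and measure every
    cohort-level quantity of interest."""
    out = process_cohort(seed=seed)
    coh = out["cohort"]
    m = coh[coh.sex == "M"]
    f = coh[coh.sex == "F"]
    margins = regression_margins(coh)
    return {
        "male_mvpa_median": float(m.mvpa_min.median()),
        "female_mvpa_median": float(f.mvpa_min.median()),
        "female_sedentary_median": float(f.sedentary_min.median()),
        "male_sedentary_median": float(m.sedentary_min.median()),
        "cdc_active_pct": float(100 * coh.active_cdc.mean()),
        "cdc_active_male_pct": float(100 * m.active_cdc.mean()),
        "cdc_active_female_pct": float(100 * f.active_cdc.mean()),
        "who_active_male_pct": float(100 * m.active_who.mean()),
        "who_active_female_pct": float(100 * f.active_who.mean()),
        "male_vo2max_median": float(m.vo2max.median()),
        "female_vo2max_median": float(f.vo2max.median()),
        "fit_mvpa_margin": float(margins["fit"]),
        "unfit_mvpa_margin": float(margins["unfit"]),
        "n_valid": float(len(coh)),
    }


def replicate_cohort_metrics(base_seed: int, n_reps: int = 10
                             ) -> dict[str, float]:
    """Monte-Carlo mean of every cohort metric over replicate cohorts
    seeded base_seed, base_seed+1, ..."""
    runs = [cohort_run_metrics(base_seed + k) for k in range(n_reps)]
    return {key: float(np.mean([r[key] for r in runs])) for key in runs[0]}


def regression_recovery(seed: int, n_total: int = 5000) -> dict[str, float]:
    """Fit the VO2max multiple regression to one large synthetic cohort.

    The cohort keeps the default 137:119 male:female ratio; MVPA and
    sedentary time are the pipeline-computed values and VO2max the
    step-test estimate, so the fit sees the same measurement chain as the
    reference analysis.  Returns coefficients, their standard errors and
    the model R^2.
    """
    n_male = round(n_total * 137 / 256)
    cfg = replace(CohortConfig(), n_male=n_male, n_female=n_total - n_male,
                  seed=seed)
    out = process_cohort(cfg)
    reg = multiple_regression(out["cohort"], "vo2max", REGRESSION_PREDICTORS)
    coefs = dict(zip(reg.predictor, reg.coef))
    bse = reg.attrs["bse"]
    return {
        "mvpa_coef": coefs["mvpa_min"], "mvpa_se": bse["mvpa_min"],
        "bmi_coef": coefs["bmi"], "bmi_se": bse["bmi"],
        "male_coef": coefs["sex"], "male_se": bse["sex"],
        "sedentary_coef": coefs["sedentary_min"],
        "r2": reg.attrs["r2"], "n": float(reg.attrs["n"]),
    }


def steptest_recovery(seed: int, n_participants: int = 200,
                      hr_noise_sd: float = 3.0) -> dict[str, float]:
    """Invert simulated step tests and measure the estimation error.

    Returns the maximum relative error over noise-free traces and the
    median absolute error at the given HR noise.
    """
    cfg = CohortConfig()
    run_cfg = RunConfig()
    rng = np.random.default_rng(seed)
    rel_err_free, abs_err_noisy = [], []
    for i in range(n_participants):
        p = sample_participant(cfg, "M" if i % 2 else "F", rng,
                               pid=f"S{i:04d}")
        clean = simulate_step_test(p, run_cfg, 0.0, rng)
        est = estimate_vo2max(clean, run_cfg)
        rel_err_free.append(abs(est.vo2max - p.true_vo2max) / p.true_vo2max)
        noisy = simulate_step_test(p, run_cfg, hr_noise_sd, rng)
        est = estimate_vo2max(noisy, run_cfg)
        abs_err_noisy.append(abs(est.vo2max - p.true_vo2max))
    return {
        "noise_free_max_rel_err": float(np.max(rel_err_free)),
        "noisy_median_abs_err": float(np.median(abs_err_noisy)),
        "n": float(n_participants),
    }
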