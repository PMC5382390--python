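#!/usr/bin/env python
"""Sex-stratified statistics on the joined cohort table.

Joins anthropometry, processed activity and fitness estimates; labels
fitness by the sex-specific median split; then reproduces the analysis
layer: descriptives by sex with between-sex tests, univariate and
multiple regression of VO2max, BMI-adjusted MVPA margins by fitness
category, and ANOVA of VO2max across BMI categories with Bonferroni
post hoc tests.  Writes CSV tables and prints a text report.

    python analysis/04_cohort_statistics.py [--cohort scratch/cohort]
        [--results results]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from actifit.config import load_config
from actifit.io import read_cohort_table
from actifit.stats import (anova_bmi, build_cohort_table, compare_proportions,
                           describe_by_sex, multiple_regression,
                           regression_margins, univariate_regressions)

PARAMETRIC = ["height_m", "weight_kg", "bmi", "vo2max"]
NONPARAMETRIC = ["mean_cpm", "sedentary_min", "light_min", "moderate_min",
                 "vigorous_min", "mvpa_min"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--config", type=Path, default=None)
    args = ap.parse_args()
    cfg = load_config(args.config)

    anthro = read_cohort_table(args.cohort / "anthropometry.csv")
    activity = pd.read_csv(args.results / "participant_activity.csv")
    fitness = pd.read_csv(args.results / "fitness_estimates.csv")
    cohort = build_cohort_table(anthro, activity[activity.valid], fitness)
    cohort.to_csv(args.results / "cohort_table.csv", index=False)
    print(f"cohort table: {len(cohort)} participants "
          f"({(cohort.sex == 'M').sum()} M, {(cohort.sex == 'F').sum()} F)")

    # descriptives by sex (reference-table layout)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for var, kind in ([(v, "parametric") for v in PARAMETRIC]
                      + [(v, "nonparametric") for v in NONPARAMETRIC]):
        res = describe_by_sex(cohort, var, kind, cfg, rng)
        rows.append({"variable": var, "kind": kind,
                     "male": res["M"].estimate, "male_ci_low": res["M"].ci_low,
                     "male_ci_high": res["M"].ci_high,
                     "female": res["F"].estimate,
                     "female_ci_low": res["F"].ci_low,
                     "female_ci_high": res["F"].ci_high,
                     "p": res["M"].p_value, "test": res["M"].test})
        print(f"{var:15s} M {res['M'].estimate:7.2f}  F {res['F'].estimate:7.2f}"
              f"  p={res['M'].p_value:.2g}")
    chi = compare_proportions(cohort, "bmi_category")
    print(f"BMI category by sex: chi2={chi.estimate:.1f} p={chi.p_value:.2g}")
    pd.DataFrame(rows).to_csv(args.results / "descriptives_by_sex.csv",
                              index=False)

    # regressions of VO2max
    uni = univariate_regressions(
        cohort, "vo2max",
        ["bmi", "height_m", "weight_kg", "mvpa_min", "sedentary_min", "sex"],
        cfg)
    uni.to_csv(args.results / "univariate_regressions.csv", index=False)
    significant = uni.loc[uni.p < cfg.alpha, "exposure"].tolist()
    print(f"significant univariate correlates (p<{cfg.alpha}): {significant}")

    # height and weight are algebraically redundant with BMI (= w/h^2), so
    # like the reference workflow they are excluded as collinear
    # anthropometry; sedentary time is retained as an exposure of interest
    predictors = [p for p in ["sedentary_min", "mvpa_min", "bmi", "sex"]
                  if p in significant or p == "sedentary_min"]
    reg = multiple_regression(cohort, "vo2max", predictors, cfg)
    reg.to_csv(args.results / "multiple_regression.csv", index=False)
    print("multiple regression of VO2max "
          f"(r2={reg.attrs['r2']:.2f}, n={reg.attrs['n']}):")
    for _, r in reg.iterrows():
        note = f"  [{r['note']}]" if r["note"] else ""
        coef = "  dropped " if np.isnan(r["coef"]) else f"{r['coef']:9.3f}"
        print(f"  {r['predictor']:15s} {coef}{note}")

    margins = regression_margins(cohort)
    bmi_margins = regression_margins(cohort, outcome="bmi", factor="fitness",
                                     covariate="mvpa_min")
    print(f"BMI-adjusted MVPA margins: fit {margins['fit']:.0f}, "
          f"unfit {margins['unfit']:.0f} min/day")
    print(f"MVPA-adjusted BMI margins: fit {bmi_margins['fit']:.2f}, "
          f"unfit {bmi_margins['unfit']:.2f} kg/m^2")
    pd.DataFrame([{"margin": "mvpa_fit", "value": margins["fit"]},
                  {"margin": "mvpa_unfit", "value": margins["unfit"]},
                  {"margin": "bmi_fit", "value": bmi_margins["fit"]},
                  {"margin": "bmi_unfit", "value": bmi_margins["unfit"]}]
                 ).to_csv(args.results / "regression_margins.csv", index=False)

    # VO2max across BMI categories
    anova = anova_bmi(cohort)
    rows = []
    for sex, res in anova.items():
        print(f"ANOVA VO2max ~ BMI category ({sex}): "
              f"F={res['F']:.1f} p={res['p']:.2g}")
        for (a, b), p in res["pairwise_bonferroni"].items():
            rows.append({"sex": sex, "group_a": a, "group_b": b,
                         "p_bonferroni": p})
    pd.DataFrame(rows).to_csv(args.results / "anova_bmi_pairwise.csv",
                              index=False)


if __name__ == "__main__":
    main()
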