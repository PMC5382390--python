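"""Sex-stratified cohort statistics.

Descriptives with 95% CIs (t-based means for parametric variables,
bootstrap-percentile medians for skewed ones), between-sex comparisons
(Student's t, Mann-Whitney U, chi-squared), univariate and multiple OLS
regression of VO2max on activity and anthropometry, BMI-adjusted
regression margins of MVPA by fitness category, and one-way ANOVA of
VO2max across BMI categories with Bonferroni-adjusted pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .config import RunConfig

BMI_CATEGORIES = ["underweight", "normal", "overweight", "obese"]


def bmi_category(bmi: float) -> str:
    """WHO 4-way partition at 18.5 / 25 / 30 kg/m^2."""
    if bmi <= 0:
        raise ValueError(f"non-positive BMI {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


@dataclass
class StatResult:
    """A point estimate with CI and the p of a two-group comparison."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    n: int


def build_cohort_table(anthro: pd.DataFrame, activity: pd.DataFrame,
                       fitness: pd.DataFrame) -> pd.DataFrame:
    """Join anthropometry, activity summaries and fitness estimates.

    One row per participant with valid data in all three inputs; adds
    ``bmi``, ``bmi_category`` and the sex-specific ``fitness`` median-split
    label.
    """
    from .steptest import classify_fitness

    df = anthro.merge(activity, on="id").merge(fitness, on="id")
    df["bmi"] = df["weight_kg"] / df["height_m"] ** 2
    df["bmi_category"] = df["bmi"].map(bmi_category)
    df["fitness"] = classify_fitness(df["vo2max"].to_numpy(),
                                     df["sex"].to_numpy())
    return df


def _mean_ci(x: np.ndarray, alpha: float) -> tuple[float, float, float]:
    m = float(np.mean(x))
    se = float(sps.sem(x))
    half = float(sps.t.ppf(1 - alpha / 2, len(x) - 1)) * se
    return m, m - half, m + half


def _median_boot_ci(x: np.ndarray, alpha: float, reps: int,
                    rng: np.random.Generator) -> tuple[float, float, float]:
    med = float(np.median(x))
    idx = rng.integers(0, len(x), size=(reps, len(x)))
    boots = np.median(np.asarray(x)[idx], axis=1)
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return med, float(lo), float(hi)


def describe_by_sex(tbl: pd.DataFrame, variable: str, kind: str = "parametric",
                    cfg: RunConfig | None = None,
                    rng: np.random.Generator | None = None
                    ) -> dict[str, StatResult]:
    """Per-sex estimate with CI plus a two-sided between-sex comparison.

    ``kind='parametric'``: mean, t-based CI, Student's t comparison.
    ``kind='nonparametric'``: median, seeded bootstrap percentile CI,
    Mann-Whitney U (exact for n<=20 without ties, else asymptotic with tie
    correction).
    """
    cfg = cfg or RunConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    groups = {s: tbl.loc[tbl["sex"] == s, variable].dropna().to_numpy()
              for s in ("M", "F")}
    for s, x in groups.items():
        if len(x) < 2:
            raise ValueError(f"need >=2 per sex, got {len(x)} for {s}")

    xm, xf = groups["M"], groups["F"]
    if kind == "parametric":
        if np.ptp(xm) == 0 and np.ptp(xf) == 0:
            p = float("nan")
        else:
            p = float(sps.ttest_ind(xm, xf).pvalue)
        test = "Student t"
        est = {s: _mean_ci(x, cfg.alpha) for s, x in groups.items()}
    elif kind == "nonparametric":
        small = max(len(xm), len(xf)) <= 20
        method = "exact" if small and not _has_ties(xm, xf) else "asymptotic"
        p = float(sps.mannwhitneyu(xm, xf, alternative="two-sided",
                                   method=method).pvalue)
        test = f"Mann-Whitney U ({method})"
        est = {s: _median_boot_ci(x, cfg.alpha, cfg.bootstrap_reps, rng)
               for s, x in groups.items()}
    else:
        raise ValueError(f"kind must be parametric|nonparametric, got {kind!r}")

    return {s: StatResult(estimate=e, ci_low=lo, ci_high=hi, p_value=p,
                          test=test, n=len(groups[s]))
            for s, (e, lo, hi) in est.items()}


def _has_ties(*arrays: np.ndarray) -> bool:
    allv = np.concatenate(arrays)
    return len(np.unique(allv)) < len(allv)


def compare_proportions(tbl: pd.DataFrame, variable: str) -> StatResult:
    """Pearson chi-squared (no continuity correction) of variable x sex."""
    ct = pd.crosstab(tbl[variable], tbl["sex"])
    return chi_squared(ct.to_numpy())


def chi_squared(observed: np.ndarray) -> StatResult:
    observed = np.asarray(observed, dtype=float)
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("empty row or column in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(observed, correction=False)
    return StatResult(estimate=float(chi2), ci_low=float("nan"),
                      ci_high=float("nan"), p_value=float(p),
                      test=f"chi-squared (dof={dof})", n=int(observed.sum()))


def univariate_regressions(tbl: pd.DataFrame, outcome: str,
                           exposures: list[str],
                           cfg: RunConfig | None = None) -> pd.DataFrame:
    """One OLS of ``outcome`` per exposure; constant exposures are skipped."""
    cfg = cfg or RunConfig()
    rows = []
    for exp in exposures:
        sub = tbl[[outcome, exp]].dropna()
        x = _numeric(sub[exp])
        if np.ptp(x) == 0:
            rows.append({"exposure": exp, "coef": np.nan, "p": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "r2": np.nan,
                         "n": len(sub), "note": "constant exposure, skipped"})
            continue
        X = sm.add_constant(x)
        fit = sm.OLS(sub[outcome].to_numpy(), X).fit()
        lo, hi = fit.conf_int(alpha=cfg.alpha)[1]
        rows.append({"exposure": exp, "coef": float(fit.params[1]),
                     "p": float(fit.pvalues[1]), "ci_low": float(lo),
                     "ci_high": float(hi), "r2": float(fit.rsquared),
                     "n": int(fit.nobs), "note": ""})
    return pd.DataFrame(rows)


def _numeric(col: pd.Series) -> np.ndarray:
    if col.dtype == object:
        uniq = sorted(col.unique())
        if set(uniq) <= {"M", "F"}:
            return (col == "M").to_numpy(dtype=float)   # male coded 1
        raise ValueError(f"cannot code column {col.name!r} numerically")
    return col.to_numpy(dtype=float)


def screen_collinearity(tbl: pd.DataFrame, predictors: list[str],
                        r_max: float = 0.7) -> tuple[list[str], list[str]]:
    """Keep predictors in order, dropping any with pairwise |r| > r_max
    against an already retained one (operationalises excluding collinear
    anthropometry such as height and weight once BMI is in the model)."""
    kept: list[str] = []
    dropped: list[str] = []
    cols = {p: _numeric(tbl[p]) for p in predictors}
    for p in predictors:
        collides = any(
            abs(np.corrcoef(cols[p], cols[q])[0, 1]) > r_max for q in kept)
        (dropped if collides else kept).append(p)
    return kept, dropped


def multiple_regression(tbl: pd.DataFrame, outcome: str,
                        predictors: list[str],
                        cfg: RunConfig | None = None) -> pd.DataFrame:
    """OLS of ``outcome`` on the predictors after a collinearity screen.

    Sex is coded male=1.  Returns one row per retained predictor plus an
    ``r2`` row; dropped predictors appear with a note.
    """
    cfg = cfg or RunConfig()
    sub = tbl[[outcome] + predictors].dropna()
    if len(sub) <= len(predictors) + 2:
        raise ValueError("too few rows for the requested model")
    kept, dropped = screen_collinearity(sub, predictors, cfg.collinearity_r_max)
    X = np.column_stack([_numeric(sub[p]) for p in kept])
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design matrix over columns {kept}")
    fit = sm.OLS(sub[outcome].to_numpy(), X).fit()
    ci = fit.conf_int(alpha=cfg.alpha)
    rows = [{"predictor": "intercept", "coef": float(fit.params[0]),
             "p": float(fit.pvalues[0]), "ci_low": float(ci[0][0]),
             "ci_high": float(ci[0][1]), "note": ""}]
    for i, p in enumerate(kept, start=1):
        rows.append({"predictor": p, "coef": float(fit.params[i]),
                     "p": float(fit.pvalues[i]), "ci_low": float(ci[i][0]),
                     "ci_high": float(ci[i][1]), "note": ""})
    for p in dropped:
        rows.append({"predictor": p, "coef": np.nan, "p": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan,
                     "note": f"dropped: |r| > {cfg.collinearity_r_max} with retained predictor"})
    out = pd.DataFrame(rows)
    out.attrs["r2"] = float(fit.rsquared)
    out.attrs["n"] = int(fit.nobs)
    out.attrs["bse"] = {p: float(fit.bse[i]) for i, p in enumerate(["intercept"] + kept)}
    return out


def regression_margins(tbl: pd.DataFrame, outcome: str = "mvpa_min",
                       factor: str = "fitness",
                       covariate: str = "bmi") -> dict[str, float]:
    """Covariate-adjusted group means: fit OLS outcome ~ factor + covariate
    and predict each factor level at the grand-mean covariate."""
    sub = tbl[[outcome, factor, covariate]].dropna()
    levels = sorted(sub[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    d = np.column_stack([
        (sub[factor] == lev).to_numpy(dtype=float) for lev in levels[1:]])
    X = sm.add_constant(np.column_stack([d, _numeric(sub[covariate])]))
    fit = sm.OLS(sub[outcome].to_numpy(), X).fit()
    cbar = float(_numeric(sub[covariate]).mean())
    margins = {}
    for i, lev in enumerate(levels):
        row = np.zeros(X.shape[1])
        row[0] = 1.0
        if i > 0:
            row[i] = 1.0
        row[-1] = cbar
        margins[lev] = float(row @ fit.params)
    return margins


def anova_bmi(tbl: pd.DataFrame, outcome: str = "vo2max"
              ) -> dict[str, dict[str, object]]:
    """Per sex: one-way ANOVA of ``outcome`` across BMI categories plus all
    pairwise Student's t comparisons with Bonferroni-multiplied p values
    (capped at 1).  Categories with n < 2 are excluded with a warning."""
    import warnings

    results: dict[str, dict[str, object]] = {}
    for s in sorted(tbl["sex"].unique()):
        sub = tbl[tbl["sex"] == s]
        groups = {}
        for cat in BMI_CATEGORIES:
            x = sub.loc[sub["bmi_category"] == cat, outcome].dropna().to_numpy()
            if 0 < len(x) < 2:
                warnings.warn(f"BMI category {cat!r} ({s}) has n<2; excluded",
                              stacklevel=2)
            elif len(x) >= 2:
                groups[cat] = x
        if len(groups) < 2:
            raise ValueError(f"fewer than 2 usable BMI categories for sex {s}")
        f, p = sps.f_oneway(*groups.values())
        pairs = list(combinations(groups, 2))
        pairwise = {}
        for a, b in pairs:
            praw = float(sps.ttest_ind(groups[a], groups[b]).pvalue)
            pairwise[(a, b)] = min(praw * len(pairs), 1.0)
        results[s] = {"F": float(f), "p": float(p),
                      "group_means": {c: float(np.mean(x)) for c, x in groups.items()},
                      "pairwise_bonferroni": pairwise}
    return results
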