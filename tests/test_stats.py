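"""Statistics layer: oracles for each test, regression exactness, margins."""

import numpy as np
import pandas as pd
import pytest

from actifit.config import RunConfig
from actifit.stats import (anova_bmi, bmi_category, chi_squared,
                           compare_proportions, describe_by_sex,
                           multiple_regression, regression_margins,
                           screen_collinearity, univariate_regressions)


class TestBMICategory:
    @pytest.mark.parametrize("bmi,label", [
        (17.0, "underweight"), (18.5, "normal"), (24.999, "normal"),
        (25.0, "overweight"), (29.999, "overweight"), (30.0, "obese"),
    ])
    def test_boundaries(self, bmi, label):
        assert bmi_category(bmi) == label

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            bmi_category(0.0)

    def test_partition_covers_generated_anthropometry(self, cohort_cfg):
        from actifit.synthetic import sample_cohort
        people = sample_cohort(cohort_cfg, np.random.default_rng(2))
        cats = [bmi_category(p.bmi) for p in people]
        assert len(cats) == len(people)      # total partition: nobody unlabelled
        assert set(cats) <= {"underweight", "normal", "overweight", "obese"}


def toy_table(xm, xf, var="vo2max"):
    return pd.DataFrame({
        "sex": ["M"] * len(xm) + ["F"] * len(xf),
        var: list(xm) + list(xf),
    })


class TestDescribeBySex:
    def test_t_statistic_matches_hand_computation(self):
        xm, xf = [10.0, 12.0, 14.0], [9.0, 11.0, 16.0]
        res = describe_by_sex(toy_table(xm, xf), "vo2max", "parametric")
        # pooled-variance Student t computed from first principles
        mm, mf = np.mean(xm), np.mean(xf)
        sp2 = (np.sum((xm - mm) ** 2) + np.sum((xf - mf) ** 2)) / 4
        t = (mm - mf) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        from scipy.stats import t as tdist
        p_hand = 2 * tdist.sf(abs(t), 4)
        assert res["M"].p_value == pytest.approx(p_hand, rel=1e-12)
        assert res["M"].estimate == pytest.approx(12.0)

    def test_identical_groups_zero_difference(self):
        res = describe_by_sex(toy_table([5, 6, 7], [5, 6, 7]), "vo2max")
        assert res["M"].estimate == res["F"].estimate

    def test_zero_variance_flagged(self):
        res = describe_by_sex(toy_table([5, 5, 5], [5, 5, 5]), "vo2max")
        assert np.isnan(res["M"].p_value)

    def test_nonparametric_median_and_ci_order(self):
        rng = np.random.default_rng(0)
        tbl = toy_table(rng.lognormal(3, 0.5, 40), rng.lognormal(2.5, 0.5, 40))
        res = describe_by_sex(tbl, "vo2max", "nonparametric")
        for s in ("M", "F"):
            r = res[s]
            assert r.ci_low <= r.estimate <= r.ci_high
            x = tbl.loc[tbl.sex == s, "vo2max"]
            assert r.estimate == pytest.approx(np.median(x))
        assert res["M"].p_value < 0.05

    def test_null_p_values_are_uniform(self):
        """Type-I calibration: under a common distribution the comparison
        p-value is Uniform(0,1)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(400):
            tbl = toy_table(rng.normal(0, 1, 25), rng.normal(0, 1, 25))
            ps.append(describe_by_sex(tbl, "vo2max").pop("M").p_value)
        assert kstest(ps, "uniform").pvalue > 1e-3


class TestChiSquared:
    def test_balanced_table_is_null(self):
        res = chi_squared(np.array([[10, 10], [10, 10]]))
        assert res.estimate == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_reference_bmi_category_split_is_significant(self):
        # observed category counts by sex from the modelled cohort report
        # (underweight/normal/overweight/obese as % of 218 M and 191 F)
        males = [37, 164, 13, 4]
        females = [23, 101, 50, 17]
        res = chi_squared(np.array([males, females]).T)
        assert res.p_value < 0.001

    def test_matches_sum_of_squares_oracle(self, rng):
        obs = rng.integers(5, 40, size=(3, 2)).astype(float)
        res = chi_squared(obs)
        expected = obs.sum(1, keepdims=True) * obs.sum(0) / obs.sum()
        chi2_hand = ((obs - expected) ** 2 / expected).sum()
        assert res.estimate == pytest.approx(chi2_hand, rel=1e-12)

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chi_squared(np.array([[0, 5], [0, 3]]))

    def test_compare_proportions_wraps_crosstab(self):
        tbl = pd.DataFrame({"sex": ["M"] * 6 + ["F"] * 6,
                            "active": [1, 1, 1, 1, 0, 0, 1, 0, 0, 0, 0, 0]})
        res = compare_proportions(tbl, "active")
        assert 0 < res.p_value < 1


class TestUnivariate:
    def test_identity_exposure(self):
        tbl = pd.DataFrame({"vo2max": [1.0, 2, 3, 4], "x": [1.0, 2, 3, 4]})
        res = univariate_regressions(tbl, "vo2max", ["x"])
        assert res.loc[0, "coef"] == pytest.approx(1.0)
        assert res.loc[0, "r2"] == pytest.approx(1.0)

    def test_slope_equals_cov_over_var_oracle(self, rng):
        tbl = pd.DataFrame({"vo2max": rng.normal(40, 5, 50),
                            "x": rng.normal(0, 2, 50)})
        res = univariate_regressions(tbl, "vo2max", ["x"])
        oracle = (np.cov(tbl.x, tbl.vo2max, ddof=1)[0, 1]
                  / np.var(tbl.x, ddof=1))
        assert res.loc[0, "coef"] == pytest.approx(oracle, rel=1e-10)

    def test_constant_exposure_skipped(self):
        tbl = pd.DataFrame({"vo2max": [1.0, 2, 3], "x": [5.0, 5, 5]})
        res = univariate_regressions(tbl, "vo2max", ["x"])
        assert np.isnan(res.loc[0, "coef"])
        assert "skipped" in res.loc[0, "note"]


class TestMultipleRegression:
    def test_noise_free_outcome_recovered_exactly(self, rng):
        n = 60
        tbl = pd.DataFrame({
            "sedentary_min": rng.normal(550, 40, n),
            "mvpa_min": rng.normal(60, 20, n),
            "bmi": rng.normal(22, 3, n),
            "sex": rng.choice(["M", "F"], n),
        })
        tbl["vo2max"] = (38.0 + 0.03 * tbl.mvpa_min - 0.30 * tbl.bmi
                         + 7.52 * (tbl.sex == "M") + 0.0 * tbl.sedentary_min)
        reg = multiple_regression(tbl, "vo2max",
                                  ["sedentary_min", "mvpa_min", "bmi", "sex"])
        coefs = dict(zip(reg.predictor, reg.coef))
        assert coefs["mvpa_min"] == pytest.approx(0.03, abs=1e-10)
        assert coefs["bmi"] == pytest.approx(-0.30, abs=1e-10)
        assert coefs["sex"] == pytest.approx(7.52, abs=1e-10)
        assert coefs["sedentary_min"] == pytest.approx(0.0, abs=1e-10)
        assert reg.attrs["r2"] == pytest.approx(1.0)

    def test_r2_equals_sum_of_squares_oracle(self, rng):
        n = 80
        tbl = pd.DataFrame({"x": rng.normal(0, 1, n), "z": rng.normal(0, 1, n)})
        tbl["vo2max"] = tbl.x + rng.normal(0, 1, n)
        reg = multiple_regression(tbl, "vo2max", ["x", "z"])
        X = np.column_stack([np.ones(n), tbl.x, tbl.z])
        beta, *_ = np.linalg.lstsq(X, tbl.vo2max, rcond=None)
        resid = tbl.vo2max - X @ beta
        r2_hand = 1 - (resid ** 2).sum() / ((tbl.vo2max - tbl.vo2max.mean()) ** 2).sum()
        assert reg.attrs["r2"] == pytest.approx(r2_hand, rel=1e-10)

    def test_collinear_predictor_dropped_with_note(self, rng):
        n = 50
        w = rng.normal(62, 10, n)
        tbl = pd.DataFrame({"weight": w, "weight_lb": w * 2.2046,
                            "mvpa_min": rng.normal(60, 20, n)})
        tbl["vo2max"] = 40 + 0.03 * tbl.mvpa_min + rng.normal(0, 1, n)
        reg = multiple_regression(tbl, "vo2max",
                                  ["weight", "mvpa_min", "weight_lb"])
        row = reg[reg.predictor == "weight_lb"].iloc[0]
        assert "dropped" in row["note"]
        kept, dropped = screen_collinearity(tbl, ["weight", "weight_lb"])
        assert kept == ["weight"] and dropped == ["weight_lb"]

    def test_singular_design_raises(self):
        tbl = pd.DataFrame({"c": [1.0] * 10, "vo2max": np.arange(10.0)})
        with pytest.raises(ValueError, match="singular"):
            multiple_regression(tbl, "vo2max", ["c"])


class TestMargins:
    def test_zero_covariate_effect_reduces_to_group_means(self):
        """When the covariate coefficient is exactly zero the adjusted
        margins are the raw group means."""
        tbl = pd.DataFrame({
            "fitness": ["fit"] * 4 + ["unfit"] * 4,
            "mvpa_min": [70.0, 70, 70, 70, 50, 50, 50, 50],
            "bmi": [21.0, 23, 21, 23, 21, 23, 21, 23],
        })
        m = regression_margins(tbl)
        assert m["fit"] == pytest.approx(70.0)
        assert m["unfit"] == pytest.approx(50.0)

    def test_matches_predict_at_grand_mean_oracle(self, rng):
        n = 60
        tbl = pd.DataFrame({
            "fitness": rng.choice(["fit", "unfit"], n),
            "bmi": rng.normal(22, 3, n),
        })
        tbl["mvpa_min"] = (60 + 12 * (tbl.fitness == "fit")
                           - 1.5 * tbl.bmi + rng.normal(0, 5, n))
        m = regression_margins(tbl)
        X = np.column_stack([np.ones(n), (tbl.fitness == "unfit").astype(float),
                             tbl.bmi])
        beta, *_ = np.linalg.lstsq(X, tbl.mvpa_min, rcond=None)
        cbar = tbl.bmi.mean()
        assert m["fit"] == pytest.approx(beta[0] + beta[2] * cbar, rel=1e-9)
        assert m["unfit"] == pytest.approx(beta[0] + beta[1] + beta[2] * cbar,
                                           rel=1e-9)
        assert m["fit"] > m["unfit"]

    def test_single_level_factor_rejected(self):
        tbl = pd.DataFrame({"fitness": ["fit"] * 5,
                            "mvpa_min": np.arange(5.0), "bmi": np.ones(5)})
        with pytest.raises(ValueError, match="single level"):
            regression_margins(tbl)


class TestANOVA:
    def _tbl(self, groups):
        rows = []
        for cat, values in groups.items():
            for v in values:
                rows.append({"sex": "M", "bmi_category": cat, "vo2max": v})
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        tbl = self._tbl({"normal": [40, 41, 42], "overweight": [40, 41, 42],
                         "obese": [40, 41, 42]})
        res = anova_bmi(tbl)["M"]
        assert res["F"] == pytest.approx(0.0)
        assert all(p == 1.0 for p in res["pairwise_bonferroni"].values())

    def test_f_matches_mean_square_oracle(self):
        groups = {"normal": [44.0, 46, 45], "overweight": [40.0, 41, 39],
                  "obese": [35.0, 37, 36]}
        res = anova_bmi(self._tbl(groups))["M"]
        allv = np.concatenate(list(groups.values()))
        gm = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - gm) ** 2 for g in groups.values())
        ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2)
                  for g in groups.values())
        f_hand = (ssb / 2) / (ssw / 6)
        assert res["F"] == pytest.approx(f_hand, rel=1e-10)
        # Bonferroni never lowers a p-value and never exceeds 1
        from scipy.stats import ttest_ind
        for (a, b), p_adj in res["pairwise_bonferroni"].items():
            praw = ttest_ind(groups[a], groups[b]).pvalue
            assert praw <= p_adj <= 1.0

    def test_small_category_excluded_with_warning(self):
        tbl = self._tbl({"normal": [44.0, 46, 45], "obese": [35.0, 37],
                         "underweight": [47.0]})
        with pytest.warns(UserWarning, match="excluded"):
            res = anova_bmi(tbl)["M"]
        assert set(res["group_means"]) == {"normal", "obese"}

    def test_generated_cohort_normal_fitter_than_obese(self, cohort_cfg):
        """The generative BMI coefficient makes normal-weight participants
        fitter than obese ones within each sex."""
        from actifit.stats import bmi_category
        from actifit.synthetic import sample_cohort
        from dataclasses import replace
        cfg = replace(cohort_cfg, n_male=2000, n_female=2000, seed=31)
        people = sample_cohort(cfg, np.random.default_rng(cfg.seed))
        tbl = pd.DataFrame({
            "sex": [p.sex for p in people],
            "bmi_category": [bmi_category(p.bmi) for p in people],
            "vo2max": [p.true_vo2max for p in people],
        })
        res = anova_bmi(tbl)
        for s in ("M", "F"):
            means = res[s]["group_means"]
            assert means["normal"] > means["obese"]
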