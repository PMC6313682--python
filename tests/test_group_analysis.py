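import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import fisher_2x2_p
from kosem.group_analysis import (
    GroupAnalysisError,
    GroupLabeling,
    check_collinearity,
    fisher_exact,
    fit_logistic,
    label_top_fraction,
    table1_frame,
    univariate_screen,
)


def exposures_series(values, prefix="s"):
    return pd.Series(values,
                     index=[f"{prefix}{i + 1:05d}" for i in range(len(values))])


class TestLabeling:
    @pytest.mark.parametrize("n,expected_high", [(8072, 404), (100, 5), (60, 3)])
    def test_top_five_percent_count_is_ceiling(self, n, expected_high):
        rng = np.random.default_rng(0)
        lab = label_top_fraction(exposures_series(rng.normal(26, 3, n)), 0.05)
        assert lab.n_high == expected_high
        assert lab.n_low == n - expected_high

    def test_threshold_is_minimum_of_high_group(self):
        lab = label_top_fraction(exposures_series([1.0, 2.0, 3.0, 4.0, 5.0]),
                                 0.4)
        assert lab.n_high == 2
        assert lab.threshold == 4.0
        assert set(lab.labels[lab.labels == "high"].index) == {"s00004",
                                                               "s00005"}

    def test_ties_broken_by_subject_id(self):
        lab = label_top_fraction(exposures_series([5.0, 5.0, 5.0, 1.0]), 0.5)
        high = sorted(lab.labels[lab.labels == "high"].index)
        assert high == ["s00001", "s00002"]     # lowest ids among the tied

    def test_lowering_fraction_never_promotes_a_subject(self):
        rng = np.random.default_rng(1)
        ex = exposures_series(rng.normal(26, 3, 500))
        big = label_top_fraction(ex, 0.10)
        small = label_top_fraction(ex, 0.05)
        small_high = set(small.labels[small.labels == "high"].index)
        big_high = set(big.labels[big.labels == "high"].index)
        assert small_high <= big_high

    def test_fraction_bounds(self):
        ex = exposures_series([1.0, 2.0])
        for frac in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(GroupAnalysisError):
                label_top_fraction(ex, frac)


class TestFisherExact:
    def test_diagonal_table_closed_form(self):
        res = fisher_exact([[5, 0], [0, 5]])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)

    def test_matches_hypergeometric_oracle(self):
        for tab in ([[3, 1], [1, 3]], [[10, 20], [15, 5]], [[2, 7], [8, 2]],
                    [[1, 9], [9, 1]], [[12, 3], [5, 8]]):
            assert fisher_exact(tab).p_value == pytest.approx(
                fisher_2x2_p(tab), abs=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            tab = rng.integers(0, 25, (2, 2))
            if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
                continue
            assert fisher_exact(tab).p_value == pytest.approx(
                stats.fisher_exact(tab)[1], abs=1e-10)

    def test_proportional_rows_give_p_1(self):
        assert fisher_exact([[10, 20], [20, 40]]).p_value == pytest.approx(1.0)

    def test_rxc_exact_enumeration(self):
        # 3x2: compare against summing probabilities over a brute-force
        # iteration of the two free cells
        tab = np.array([[8, 2], [3, 7], [4, 6]])
        res = fisher_exact(tab)
        assert res.method == "exact"
        from scipy.special import gammaln
        rm, cm = tab.sum(1), tab.sum(0)
        const = (gammaln(rm + 1).sum() + gammaln(cm + 1).sum()
                 - gammaln(tab.sum() + 1))
        def logp(t):
            return const - gammaln(np.asarray(t) + 1).sum()
        p_obs = logp(tab)
        total = 0.0
        for a in range(rm[0] + 1):
            for b in range(rm[1] + 1):
                t = [[a, rm[0] - a], [b, rm[1] - b],
                     [cm[0] - a - b, cm[1] - (rm[0] - a) - (rm[1] - b)]]
                if min(t[2]) < 0:
                    continue
                lp = logp(t)
                if lp <= p_obs + math.log1p(1e-7):
                    total += math.exp(lp)
        assert res.p_value == pytest.approx(total, abs=1e-12)

    def test_monte_carlo_fallback_tracks_exact(self):
        tab = [[8, 2], [3, 7], [4, 6]]
        exact = fisher_exact(tab).p_value
        mc = fisher_exact(tab, budget=5, n_mc=50_000, seed=3)
        assert mc.method == "monte_carlo"
        assert abs(mc.p_value - exact) < 4 * mc.mc_se + 1e-4

    def test_degenerate_table_rejected(self):
        with pytest.raises(GroupAnalysisError, match="degenerate"):
            fisher_exact([[0, 0], [3, 4]])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 15), st.integers(1, 15), st.integers(0, 15),
           st.integers(0, 15))
    def test_transpose_invariance(self, a, b, c, d):
        tab = np.array([[a, b], [c, d]])
        if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
            return
        assert fisher_exact(tab).p_value == pytest.approx(
            fisher_exact(tab.T).p_value, abs=1e-12)


def synthetic_cohort(n, rng, beta_job=0.0, beta_hours=0.0, base=-3.2):
    cov = pd.DataFrame({
        "job": rng.choice(["office", "non_office"], n),
        "working_hours": rng.normal(40, 15, n).clip(0, 120).round(1),
        "noise": rng.normal(0, 1, n),
    }, index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"))
    lin = (base + beta_job * (cov["job"] == "non_office")
           + beta_hours * cov["working_hours"])
    y = rng.random(n) < 1 / (1 + np.exp(-lin))
    labels = pd.Series(np.where(y, "high", "low"), index=cov.index)
    lab = GroupLabeling(threshold=math.nan, labels=labels,
                        n_high=int(y.sum()), n_low=int(n - y.sum()))
    return cov, lab


class TestScreen:
    def test_alpha_in_is_a_strict_inequality(self):
        rng = np.random.default_rng(7)
        cov, lab = synthetic_cohort(800, rng, beta_job=1.0)
        frame, selected = univariate_screen(lab, cov[["job"]], alpha_in=0.1)
        p = frame.loc[frame["variable"] == "job", "p_value"].iloc[0]
        _, at_p = univariate_screen(lab, cov[["job"]], alpha_in=p)
        _, above_p = univariate_screen(lab, cov[["job"]],
                                       alpha_in=p + 1e-9)
        assert at_p == []           # p < alpha must be strict
        assert above_p == ["job"]

    def test_strong_effect_reliably_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            cov, lab = synthetic_cohort(2000, rng, beta_job=math.log(2.2))
            _, selected = univariate_screen(lab, cov[["job"]], alpha_in=0.1)
            hits += "job" in selected
        assert hits >= 19           # >= 95% of replications

    def test_noise_covariate_selected_at_nominal_rate(self):
        hits = 0
        reps = 400
        for seed in range(reps):
            rng = np.random.default_rng(2000 + seed)
            cov, lab = synthetic_cohort(400, rng, beta_job=0.0)
            _, selected = univariate_screen(lab, cov[["noise"]], alpha_in=0.1)
            hits += "noise" in selected
        rate = hits / reps
        se = math.sqrt(0.1 * 0.9 / reps)
        assert abs(rate - 0.10) < 3.5 * se

    def test_not_applicable_levels_excluded_from_tables(self):
        rng = np.random.default_rng(3)
        cov, lab = synthetic_cohort(300, rng)
        cov.loc[cov.index[:150], "job"] = "not_applicable"
        frame = table1_frame(lab, cov[["job"]])
        assert "not_applicable" not in set(frame["level"])
        assert frame["n_low"].sum() + frame["n_high"].sum() <= 150


class TestCollinearity:
    def test_orthogonal_covariates_have_unit_vif(self):
        rng = np.random.default_rng(0)
        n = 5000
        cov = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        rep = check_collinearity(cov, ["x1", "x2"], vif_threshold=10)
        assert all(abs(v - 1.0) < 0.05 for v in rep.vifs.values())
        assert rep.dropped == []

    def test_duplicated_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame({"x1": rng.normal(size=200)})
        cov["x2"] = cov["x1"]
        with pytest.warns(UserWarning, match="collinearity"):
            rep = check_collinearity(cov, ["x1", "x2"], vif_threshold=10)
        assert rep.dropped == ["x2"]        # later-ordered copy goes
        assert rep.retained_variables == ["x1"]

    def test_vif_matches_direct_regression_oracle(self):
        rng = np.random.default_rng(2)
        n = 3000
        x1 = rng.normal(size=n)
        x2 = x1 + rng.normal(scale=0.3, size=n)
        x3 = rng.normal(size=n)
        cov = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        rep = check_collinearity(cov, ["x1", "x2", "x3"], vif_threshold=50)
        import statsmodels.api as sm
        X_others = sm.add_constant(np.column_stack([x2, x3]))
        r2 = sm.OLS(x1, X_others).fit().rsquared
        assert rep.vifs["x1"] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestLogistic:
    def test_odds_ratio_is_exp_of_coefficient(self):
        rng = np.random.default_rng(5)
        cov, lab = synthetic_cohort(3000, rng, beta_job=0.7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_logistic(lab, cov, ["job", "working_hours"])
        for row in m.terms.itertuples():
            assert row.odds_ratio == pytest.approx(math.exp(row.coefficient))
            assert row.ci_low == pytest.approx(
                math.exp(row.coefficient - 1.959963984540054 * row.se))
            assert row.ci_low <= row.odds_ratio <= row.ci_high

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(6)
        cov, lab = synthetic_cohort(20_000, rng, beta_job=0.0, base=-2.0)
        m = fit_logistic(lab, cov, ["job"])
        assert m.terms["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=0.15)

    def test_coefficient_recovery_within_2se(self):
        rng = np.random.default_rng(11)
        cov, lab = synthetic_cohort(8000, rng, beta_job=0.8, beta_hours=0.028,
                                    base=-4.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_logistic(lab, cov, ["job", "working_hours"])
        t = m.terms.set_index("variable")
        assert abs(t.loc["job", "coefficient"] - 0.8) < 2 * t.loc["job", "se"]
        assert abs(t.loc["working_hours", "coefficient"] - 0.028) \
            < 2 * t.loc["working_hours", "se"]

    def test_row_permutation_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(12)
        cov, lab = synthetic_cohort(2000, rng, beta_job=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = fit_logistic(lab, cov, ["job", "working_hours"])
            perm = rng.permutation(cov.index)
            lab2 = GroupLabeling(math.nan, lab.labels.loc[perm],
                                 lab.n_high, lab.n_low)
            m2 = fit_logistic(lab2, cov.loc[perm], ["job", "working_hours"])
        assert np.allclose(m1.terms["coefficient"], m2.terms["coefficient"],
                           atol=1e-8)

    def test_lrt_approaches_wald_at_large_n(self):
        rng = np.random.default_rng(13)
        cov, lab = synthetic_cohort(100_000, rng, beta_hours=0.004, base=-2.0)
        m = fit_logistic(lab, cov, ["working_hours"])
        z = m.terms["coefficient"].iloc[0] / m.terms["se"].iloc[0]
        p_wald = 2 * stats.norm.sf(abs(z))
        assert abs(m.variable_lrt_p["working_hours"] - p_wald) < 0.01

    def test_complete_separation_reported(self):
        cov = pd.DataFrame({"x": np.r_[np.zeros(50), np.ones(50)]},
                           index=[f"s{i}" for i in range(100)])
        labels = pd.Series(np.r_[["low"] * 50, ["high"] * 50], index=cov.index)
        lab = GroupLabeling(math.nan, labels, 50, 50)
        with pytest.raises(GroupAnalysisError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_logistic(lab, cov, ["x"])
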