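"""Kaplan-Meier, log-rank, Cox and Firth fits against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immuscore import (
    cox_fit,
    firth_cox_fit,
    firth_logistic_fit,
    km_estimate,
    logrank_test,
    univariate_screen,
)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_two_subject_toy(self):
        km = km_estimate([1, 2], [1, 0])
        assert km.evaluate(1) == pytest.approx(0.5)
        assert km.evaluate(2) == pytest.approx(0.5)

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([3, 7, 9], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_five_subject_hand_product_limit(self):
        # times 1,2,3,4,5; events 1,1,0,1,0
        # S(1)=4/5, S(2)=4/5*3/4=3/5, S(3)=3/5, S(4)=3/5*1/2=3/10, S(5)=3/10
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        expected = [4 / 5, 3 / 5, 3 / 5, 3 / 10, 3 / 10]
        assert np.allclose(km.evaluate([1, 2, 3, 4, 5]), expected)
        assert km.evaluate(0.5) == 1.0  # S(0) = 1

    def test_censored_at_event_time_counted_at_risk(self):
        # death and censoring at t=2: the censored subject is at risk
        km = km_estimate([2, 2, 5], [1, 0, 1])
        assert km.evaluate(2) == pytest.approx(2 / 3)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            km_estimate([0.0, 1.0], [1, 1])

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.floats(0.1, 100, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_no_censoring_equals_empirical_survival(self, times):
        km = km_estimate(times, np.ones(len(times)))
        t = np.sort(np.asarray(times))
        ecdf_surv = 1.0 - np.searchsorted(t, km.times, side="right") / len(t)
        assert np.allclose(km.survival, ecdf_surv, atol=1e-12)

    def test_survival_non_increasing(self, small_cohort):
        km = km_estimate(
            small_cohort.survival["time_months"], small_cohort.survival["event"]
        )
        assert np.all(np.diff(km.survival) <= 1e-15)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


class TestLogRank:
    def test_identical_copies_give_zero_statistic(self):
        t = [1, 3, 5, 7]
        e = [1, 1, 0, 1]
        res = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_formula(self):
        """Direct O-E / hypergeometric-V evaluation on a tiny two-group set."""
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        e = np.array([1, 1, 1, 1, 1, 1])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        o_a, e_a, v = 0.0, 0.0, 0.0
        for ti in t:
            at_risk = t >= ti
            n = at_risk.sum()
            n_a = (at_risk & (g == "a")).sum()
            dying = t == ti
            d = dying.sum()
            o_a += (dying & (g == "a")).sum()
            e_a += d * n_a / n
            if n > 1:
                v += d * (n - d) / (n - 1) * (n_a / n) * (1 - n_a / n)
        expected = (o_a - e_a) ** 2 / v
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_group_relabeling_invariance(self, toy_survival):
        df = toy_survival
        a = logrank_test(df["time_months"], df["event"], df["x"])
        b = logrank_test(df["time_months"], df["event"], 1 - df["x"])
        assert a.statistic == pytest.approx(b.statistic)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_against_exhaustive_permutation_at_n8(self):
        """With all events and no censoring the log-rank p is calibrated
        against the exhaustive permutation distribution of the statistic."""
        t = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        e = np.ones(8, dtype=int)
        g_obs = np.array([1, 1, 0, 1, 0, 0, 1, 0])
        obs = logrank_test(t, e, g_obs).statistic
        stats_all = []
        for combo in itertools.combinations(range(8), 4):
            g = np.zeros(8, dtype=int)
            g[list(combo)] = 1
            stats_all.append(logrank_test(t, e, g).statistic)
        perm_p = np.mean(np.asarray(stats_all) >= obs - 1e-12)
        chi2_p = logrank_test(t, e, g_obs).p_value
        # permutation p is exact; the chi-square reference approximates it
        assert abs(perm_p - chi2_p) < 0.12

    def test_three_group_statistic_nonnegative_df2(self, small_cohort):
        df = small_cohort.survival
        tertile = pd.qcut(df["age"], 3, labels=["t1", "t2", "t3"])
        res = logrank_test(df["time_months"], df["event"], tertile)
        assert res.df == 2
        assert res.statistic >= 0


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def _partial_loglik_1d(beta, t, e, x):
    """Independent no-ties Cox partial log-likelihood (product form)."""
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            risk = t >= t[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_beta_matches_grid_search_maximizer(self):
        t = np.array([3, 5, 7, 9, 11, 13, 15, 17], dtype=float)
        e = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        df = pd.DataFrame({"time_months": t, "event": e, "x": x})
        fit = cox_fit(df, ["x"])
        grid = np.arange(-3, 3, 1e-4)
        ll = [_partial_loglik_1d(b, t, e, x) for b in grid]
        beta_grid = grid[int(np.argmax(ll))]
        assert abs(fit.coef[0] - beta_grid) <= 1e-3 + 1e-4

    def test_identical_groups_beta_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 0, 1, 1, 1, 0]
        x = [0, 0, 0, 0, 1, 1, 1, 1]
        fit = cox_fit(
            pd.DataFrame({"time_months": t, "event": e, "x": x}), ["x"]
        )
        assert abs(fit.coef[0]) < 1e-6

    def test_location_invariance_of_covariate(self, toy_survival):
        df = toy_survival
        a = cox_fit(df, ["x"])
        df2 = df.assign(x=df["x"] + 57.3)
        b = cox_fit(df2, ["x"])
        assert a.coef[0] == pytest.approx(b.coef[0], abs=1e-8)

    def test_matches_lifelines_efron(self, toy_survival):
        from lifelines import CoxPHFitter

        fit = cox_fit(toy_survival, ["x"])
        cph = CoxPHFitter().fit(
            toy_survival, duration_col="time_months", event_col="event"
        )
        assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(
            cph.standard_errors_["x"], abs=1e-5
        )

    def test_loglik_nondecreasing_over_iterations(self, toy_survival):
        fit = cox_fit(toy_survival, ["x"])
        assert np.all(np.diff(fit.loglik_path) >= -1e-10)

    def test_constant_covariate_named_in_error(self, toy_survival):
        df = toy_survival.assign(flat=1.0)
        with pytest.raises(ValueError, match="flat"):
            cox_fit(df, ["flat"])

    def test_no_events_is_error(self):
        df = pd.DataFrame(
            {"time_months": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]}
        )
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, ["x"])

    def test_efron_vs_breslow_on_heavily_tied_data(self):
        """Efron and Breslow corrections disagree under ties; the Efron
        estimate agrees with lifelines' (Efron) fit."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        n = 40
        x = rng.standard_normal(n).round(1)
        t = np.ceil(rng.exponential(np.exp(-0.6 * x) * 5))
        e = (rng.random(n) > 0.3).astype(int)
        df = pd.DataFrame({"time_months": t, "event": e, "x": x})
        a = cox_fit(df, ["x"], ties="efron")
        b = cox_fit(df, ["x"], ties="breslow")
        assert abs(a.coef[0] - b.coef[0]) > 1e-3
        cph = CoxPHFitter().fit(df, "time_months", "event")
        assert a.coef[0] == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_hr_and_ci_consistent(self, toy_survival):
        fit = cox_fit(toy_survival, ["x"])
        assert fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]
        assert fit.hr[0] == pytest.approx(np.exp(fit.coef[0]))


# ---------------------------------------------------------------------------
# Firth-penalized Cox
# ---------------------------------------------------------------------------


def _info_1d(beta, t, e, x):
    info = 0.0
    for i in range(len(t)):
        if e[i]:
            risk = t >= t[i]
            w = np.exp(beta * x[risk])
            s0 = w.sum()
            s1 = (w * x[risk]).sum()
            s2 = (w * x[risk] ** 2).sum()
            info += s2 / s0 - (s1 / s0) ** 2
    return info


class TestFirthCox:
    def test_monotone_likelihood_finite_and_grid_verified(self):
        """All group-A events precede all group-B events: the unpenalized
        MLE diverges; Firth's estimate is finite and matches the grid
        maximizer of the penalized partial likelihood."""
        t = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        e = np.ones(8, dtype=int)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        df = pd.DataFrame({"time_months": t, "event": e, "x": x})
        fit = firth_cox_fit(df, ["x"])
        assert np.isfinite(fit.coef[0])
        grid = np.arange(-1, 6, 1e-4)
        pll = [
            _partial_loglik_1d(b, t, e, x) + 0.5 * np.log(_info_1d(b, t, e, x))
            for b in grid
        ]
        beta_grid = grid[int(np.argmax(pll))]
        assert abs(fit.coef[0] - beta_grid) <= 1e-3 + 1e-4

    def test_balanced_null_beta_near_zero(self):
        t = [1, 2, 3, 4, 1.5, 2.5, 3.5, 4.5]
        e = [1, 1, 1, 1, 1, 1, 1, 1]
        x = [0, 1, 0, 1, 1, 0, 1, 0]
        fit = firth_cox_fit(
            pd.DataFrame({"time_months": t, "event": e, "x": x}), ["x"]
        )
        assert abs(fit.coef[0]) < 0.2

    def test_penalized_loglik_at_optimum_beats_null(self, toy_survival):
        fit = firth_cox_fit(toy_survival, ["x"])
        from immuscore.survival import _penalized_cox_fun

        fun = _penalized_cox_fun(
            toy_survival[["x"]].to_numpy(),
            toy_survival["time_months"].to_numpy(),
            toy_survival["event"].to_numpy(int),
        )
        assert fit.penalized_loglik >= fun(np.zeros(1))[0] - 1e-10

    def test_profile_ci_contains_point_estimate(self, toy_survival):
        fit = firth_cox_fit(toy_survival, ["x"])
        assert fit.ci_method == "profile"
        assert fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]

    def test_large_sample_agreement_with_unpenalized(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-0.5 * x) * 10)
        c = rng.exponential(25, n)
        df = pd.DataFrame(
            {
                "time_months": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "x": x,
            }
        )
        firth = firth_cox_fit(df, ["x"], ci="wald")
        plain = cox_fit(df, ["x"])
        assert abs(firth.coef[0] - plain.coef[0]) < 0.02


# ---------------------------------------------------------------------------
# Firth-penalized logistic
# ---------------------------------------------------------------------------


class TestFirthLogistic:
    def test_two_by_two_equals_haldane_corrected_log_or(self):
        # table: exposed 7/3 events, unexposed 2/8
        y = np.array([1] * 7 + [0] * 3 + [1] * 2 + [0] * 8)
        x = np.array([1.0] * 10 + [0.0] * 10)
        fit = firth_logistic_fit(y, x.reshape(-1, 1))
        haldane = np.log((7.5 * 8.5) / (3.5 * 2.5))
        assert abs(fit.coef[1] - haldane) < 1e-6

    def test_complete_separation_finite_slope(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x = np.array([-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0])
        fit = firth_logistic_fit(y, x.reshape(-1, 1))
        assert np.isfinite(fit.coef).all()
        assert fit.converged

    def test_intercept_only_closed_form(self):
        # k events of n: penalized maximizer has fitted p = (k+1/2)/(n+1)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        fit = firth_logistic_fit(y, np.empty((10, 0)), add_intercept=True)
        p_hat = 1.0 / (1.0 + np.exp(-fit.coef[0]))
        assert abs(p_hat - 3.5 / 11.0) < 1e-8

    def test_constant_response_still_finite(self):
        y = np.zeros(6)
        fit = firth_logistic_fit(y, np.empty((6, 0)))
        assert np.isfinite(fit.coef).all()

    def test_non_binary_response_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            firth_logistic_fit([0, 1, 2], [[1.0], [2.0], [3.0]])


# ---------------------------------------------------------------------------
# Univariable screening
# ---------------------------------------------------------------------------


class TestUnivariateScreen:
    def test_single_candidate_matches_direct_fit(self, toy_survival):
        table = univariate_screen(toy_survival, ["x"], method="cox")
        direct = cox_fit(toy_survival, ["x"])
        assert table.loc["x", "estimate"] == pytest.approx(direct.coef[0])
        assert table.loc["x", "p"] == pytest.approx(direct.p[0])

    def test_all_missing_candidate_reported_not_fatal(self, toy_survival):
        df = toy_survival.assign(empty=np.nan)
        table = univariate_screen(df, ["x", "empty"], method="cox")
        assert table.loc["empty", "error"] != ""
        assert np.isnan(table.loc["empty", "HR"])
        assert table.loc["x", "error"] == ""

    def test_logistic_screening_on_response(self, small_cohort):
        df = small_cohort.survival.assign(
            rr=(small_cohort.survival["response"] == "RR").astype(int)
        )
        table = univariate_screen(
            df, ["age"], method="firth_logistic", response_col="rr"
        )
        assert np.isfinite(table.loc["age", "estimate"])

    def test_bh_column_optional(self, toy_survival):
        df = toy_survival.assign(noise=np.arange(len(toy_survival)) % 3)
        t = univariate_screen(df, ["x", "noise"], method="cox", add_bh=True)
        assert "p_adj" in t.columns
        assert (t["p_adj"] >= t["p"] - 1e-15).all()

    def test_null_type_one_error_calibrated(self):
        """Null Cox screening rejects at ~5%: 300 replicates, one
        standard-normal candidate, exponential survival."""
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 300
        for _ in range(reps):
            n = 100
            x = rng.standard_normal(n)
            t = rng.exponential(10, n)
            c = rng.exponential(30, n)
            df = pd.DataFrame(
                {
                    "time_months": np.minimum(t, c),
                    "event": (t <= c).astype(int),
                    "x": x,
                }
            )
            tab = univariate_screen(df, ["x"], method="cox")
            rejections += tab["p"].iloc[0] < 0.05
        assert 0.02 <= rejections / reps <= 0.09
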