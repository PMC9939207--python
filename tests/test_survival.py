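import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survscore.errors import EstimationError
from survscore.simulate import SimConfig, generate_cohort
from survscore.survival import (CoxFit, fit_cox, hr_ci, km_estimate, logrank,
                                schoenfeld_test, survival_at)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------
class TestKM:
    def test_hand_product_limit(self):
        km = km_estimate([2, 4, 6], [1, 1, 1])
        assert km.times.tolist() == [2, 4, 6]
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 2, 1]

    def test_all_censored(self):
        km = km_estimate([5, 8, 13], [0, 0, 0])
        assert survival_at(km, 100.0) == 100.0

    def test_empty_error(self):
        with pytest.raises(EstimationError):
            km_estimate([], [])

    def test_censoring_after_event_at_tie(self):
        # censored subject at t=2 stays in the risk set of the death at t=2
        km = km_estimate([2, 2, 5], [1, 0, 1])
        assert km.survival[0] == pytest.approx(2 / 3)

    def test_no_censoring_equals_empirical(self, rng):
        t = rng.integers(1, 30, 200).astype(float)
        km = km_estimate(t, np.ones(200))
        for tt in [1, 5, 10, 29]:
            assert survival_at(km, tt) / 100 == pytest.approx((t > tt).mean())

    @given(st.lists(st.tuples(st.floats(0.1, 100), st.booleans()),
                    min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_survival_monotone_in_unit_interval(self, data):
        t = [d[0] for d in data]
        e = [int(d[1]) for d in data]
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))

    def test_greenwood_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(50, 300).round(1) + 0.1
        e = rng.integers(0, 2, 300)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for i, tt in enumerate(km.times):
            assert km.survival[i] == pytest.approx(
                kmf.survival_function_at_times(tt).iloc[0], abs=1e-10)


class TestSurvivalAt:
    def test_before_first_event(self):
        km = km_estimate([2, 4, 6], [1, 1, 1])
        assert survival_at(km, 1.0) == 100.0

    def test_step_lookup(self):
        km = km_estimate([2, 4, 6], [1, 1, 1])
        assert survival_at(km, 3.0) == pytest.approx(66.6667, abs=0.01)

    def test_right_continuity_at_event(self):
        km = km_estimate([2, 4, 6], [1, 1, 1])
        assert survival_at(km, 2.0) == pytest.approx(66.6667, abs=0.01)

    def test_carry_forward(self):
        km = km_estimate([2, 4, 6, 9], [1, 1, 1, 0])
        assert survival_at(km, 1e6) == pytest.approx(survival_at(km, 6.0))

    def test_negative_t_error(self):
        km = km_estimate([2], [1])
        with pytest.raises(EstimationError):
            survival_at(km, -1.0)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------
def _logrank_oracle(ta, ea, tb, eb):
    """Independent O-E / hypergeometric-variance computation, plain loops."""
    all_times = sorted({t for t, e in zip(list(ta) + list(tb), list(ea) + list(eb)) if e})
    O_minus_E = 0.0
    V = 0.0
    for u in all_times:
        n_a = sum(t >= u for t in ta)
        n_b = sum(t >= u for t in tb)
        d_a = sum(t == u and e for t, e in zip(ta, ea))
        d_b = sum(t == u and e for t, e in zip(tb, eb))
        n, d = n_a + n_b, d_a + d_b
        O_minus_E += d_b - d * n_b / n
        if n > 1:
            V += d * (n_b / n) * (n_a / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestLogrank:
    def test_identical_groups(self):
        t = [3, 5, 7, 11.0]
        e = [1, 0, 1, 1]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_oracle_small(self):
        ta, ea = [1.0, 3.0, 5.0, 7.0], [1, 1, 0, 1]
        tb, eb = [2.0, 4.0, 6.0, 8.0], [1, 0, 1, 1]
        chi2, _ = logrank(ta, ea, tb, eb)
        assert chi2 == pytest.approx(_logrank_oracle(ta, ea, tb, eb), abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        ta = rng.exponential(30, 120).round(1) + 0.1
        ea = rng.integers(0, 2, 120)
        tb = rng.exponential(45, 90).round(1) + 0.1
        eb = rng.integers(0, 2, 90)
        chi2, p = logrank(ta, ea, tb, eb)
        res = logrank_test(ta, tb, ea, eb)
        assert chi2 == pytest.approx(res.test_statistic, abs=1e-8)
        assert p == pytest.approx(res.p_value, abs=1e-10)

    def test_no_events_warns(self):
        with pytest.warns(UserWarning):
            chi2, p = logrank([1, 2], [0, 0], [3, 4], [0, 0])
        assert (chi2, p) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------
def _partial_loglik_oracle(beta, t, e, x, ties="efron"):
    """Literal partial-likelihood formula, written independently with loops."""
    ll = 0.0
    for u in sorted({tt for tt, ee in zip(t, e) if ee}):
        D = [i for i in range(len(t)) if t[i] == u and e[i]]
        R = [i for i in range(len(t)) if t[i] >= u]
        d = len(D)
        s_d = sum(np.exp(beta * x[i]) for i in D)
        s_r = sum(np.exp(beta * x[i]) for i in R)
        ll += sum(beta * x[i] for i in D)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= np.log(s_r - frac * s_d)
    return ll


class TestCox:
    toy_t = [3.0, 5.0, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0]
    toy_e = [1, 1, 1, 0, 1, 1, 0, 1]
    toy_x = [1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0]

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_grid_search_oracle(self, ties):
        fit = fit_cox(self.toy_t, self.toy_e, self.toy_x, ties=ties)
        grid = np.arange(-3.0, 3.0001, 1e-4)
        lls = [_partial_loglik_oracle(b, self.toy_t, self.toy_e, self.toy_x, ties)
               for b in grid]
        assert fit.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_loglik_matches_oracle_at_beta(self):
        fit = fit_cox(self.toy_t, self.toy_e, self.toy_x)
        # oracle uses uncentered x; partial likelihood is shift-invariant
        assert fit.loglik == pytest.approx(
            _partial_loglik_oracle(fit.beta[0], self.toy_t, self.toy_e, self.toy_x),
            abs=1e-8)

    def test_symmetric_groups_beta_zero(self):
        t = [2, 4, 6, 2, 4, 6.0]
        e = [1, 1, 1, 1, 1, 1]
        x = [0, 0, 0, 1, 1, 1.0]
        fit = fit_cox(t, e, x)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert hr_ci(fit, 0)[0] == pytest.approx(1.0)

    def test_exponential_rate_ratio_recovery(self, rng):
        n = 10000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.02 * 2.0**x))
        fit = fit_cox(t, np.ones(n), x)
        assert fit.beta[0] == pytest.approx(np.log(2), abs=0.05)

    def test_efron_breslow_agree_without_ties(self, rng):
        n = 150
        x = rng.normal(size=(n, 2))
        t = rng.exponential(10, n) + np.arange(n) * 1e-6  # guarantee distinct
        e = rng.integers(0, 2, n)
        e[0] = 1
        fe = fit_cox(t, e, x, ties="efron")
        fb = fit_cox(t, e, x, ties="breslow")
        assert fe.beta == pytest.approx(fb.beta, abs=1e-6)

    def test_loglik_at_beta_ge_null(self, derived_cohort):
        df = derived_cohort
        x = df[["smoke", "bmi"]].to_numpy(float)
        fit = fit_cox(df["time_months"], df["event"], x)
        null = fit_cox(df["time_months"], df["event"], x, max_iter=0)
        assert fit.loglik >= null.loglik

    def test_matches_lifelines(self, derived_cohort):
        import pandas as pd
        from lifelines import CoxPHFitter

        df = derived_cohort[["time_months", "event", "age", "smoke", "bmi",
                             "metabolic_syndrome"]].copy()
        fit = fit_cox(df["time_months"], df["event"],
                      df[["age", "smoke", "bmi", "metabolic_syndrome"]].to_numpy(float),
                      names=["age", "smoke", "bmi", "metabolic_syndrome"])
        cph = CoxPHFitter().fit(df, duration_col="time_months", event_col="event")
        for name in ["age", "smoke", "bmi", "metabolic_syndrome"]:
            assert fit.beta[fit.names.index(name)] == pytest.approx(
                cph.params_[name], abs=1e-4)
            assert fit.se[fit.names.index(name)] == pytest.approx(
                cph.standard_errors_[name], rel=1e-3)

    def test_constant_covariate_error(self):
        with pytest.raises(EstimationError, match="constant"):
            fit_cox([1, 2, 3.0], [1, 1, 0], [2.0, 2.0, 2.0])

    def test_monotone_likelihood_flagged(self):
        # covariate perfectly orders event times: likelihood is monotone
        t = np.arange(1.0, 21.0)
        e = np.ones(20)
        x = np.arange(20.0)
        fit = fit_cox(t, e, x)
        assert not fit.converged

    def test_no_events_error(self):
        with pytest.raises(EstimationError):
            fit_cox([1, 2.0], [0, 0], [0.0, 1.0])

    def test_covariance_symmetric_psd(self, derived_cohort):
        df = derived_cohort
        fit = fit_cox(df["time_months"], df["event"],
                      df[["age", "smoke", "bmi"]].to_numpy(float))
        assert np.allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-12)
        assert fit.se == pytest.approx(np.sqrt(np.diag(fit.cov)))


class TestHrCi:
    def test_null_coefficient_closed_form(self):
        fit = CoxFit(names=["x"], beta=np.array([0.0]), se=np.array([0.1]),
                     cov=np.array([[0.01]]), loglik=0.0, ties="efron",
                     converged=True, n=10, n_events=5)
        hr, lo, hi = hr_ci(fit, "x")
        assert hr == pytest.approx(1.0)
        assert lo == pytest.approx(0.8220, abs=1e-3)
        assert hi == pytest.approx(1.2165, abs=1e-3)

    def test_printed_ci_round_trip(self):
        # implied SE back-calculated from a published interval 1.51-2.96
        se = (np.log(2.96) - np.log(1.51)) / (2 * 1.959964)
        assert se == pytest.approx(0.172, abs=0.005)
        beta = np.log(np.sqrt(2.96 * 1.51))
        fit = CoxFit(names=["x"], beta=np.array([beta]), se=np.array([se]),
                     cov=np.array([[se**2]]), loglik=0.0, ties="efron",
                     converged=True, n=1, n_events=1)
        _, lo, hi = hr_ci(fit, "x")
        assert lo == pytest.approx(1.51, abs=0.005)
        assert hi == pytest.approx(2.96, abs=0.005)

    def test_ci_contains_hr_and_log_symmetric(self, derived_cohort):
        df = derived_cohort
        fit = fit_cox(df["time_months"], df["event"],
                      df[["smoke"]].to_numpy(float), names=["smoke"])
        hr, lo, hi = hr_ci(fit, "smoke")
        assert lo < hr < hi
        assert np.log(hi) - np.log(hr) == pytest.approx(np.log(hr) - np.log(lo))


# ---------------------------------------------------------------------------
# Schoenfeld PH test
# ---------------------------------------------------------------------------
def _sim_reversing_effect(n, seed, flip_at=50.0, beta=0.8, rate=0.02):
    """Hazard rate*exp(+beta x) before flip_at, rate*exp(-beta x) after."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    e1 = rng.exponential(1.0, n)
    t = np.empty(n)
    h1 = rate * np.exp(beta * x)
    h2 = rate * np.exp(-beta * x)
    early = e1 < h1 * flip_at
    t[early] = e1[early] / h1[early]
    t[~early] = flip_at + (e1[~early] - h1[~early] * flip_at) / h2[~early]
    cens = rng.uniform(50, 150, n)
    event = (t <= cens).astype(int)
    return np.minimum(t, cens) + 1e-9, event, x


class TestSchoenfeld:
    def test_single_event_error(self, derived_cohort):
        df = derived_cohort.head(50)
        fit = fit_cox(df["time_months"], df["event"], df[["smoke"]].to_numpy(float))
        with pytest.raises(EstimationError):
            schoenfeld_test(fit, [1.0, 2.0], [1, 0], [[0.0], [1.0]])

    def test_detects_reversing_effect(self):
        hits = 0
        for s in range(10):
            t, e, x = _sim_reversing_effect(2000, seed=s)
            fit = fit_cox(t, e, x, names=["x"])
            _, p = schoenfeld_test(fit, t, e, x)["x"]
            hits += p < 0.05
        assert hits >= 9  # > 80% power

    def test_null_specificity(self):
        keep = 0
        reps = 40
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            n = 400
            x = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)])
            t = rng.exponential(1.0 / (0.02 * np.exp(0.5 * x[:, 0])))
            e = (t <= 120).astype(int)
            t = np.minimum(t, 120.0) + 1e-9
            fit = fit_cox(t, e, x, names=["a", "b"])
            # covariate b has zero coefficient and no time trend
            _, p = schoenfeld_test(fit, t, e, x)["b"]
            keep += p > 0.05
        assert keep / reps >= 0.9

    def test_agrees_with_lifelines_direction(self, derived_cohort):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test

        df = derived_cohort[["time_months", "event", "smoke", "age"]]
        fit = fit_cox(df["time_months"], df["event"],
                      df[["smoke", "age"]].to_numpy(float), names=["smoke", "age"])
        ours = schoenfeld_test(fit, df["time_months"], df["event"],
                               df[["smoke", "age"]].to_numpy(float))
        cph = CoxPHFitter().fit(df, duration_col="time_months", event_col="event")
        theirs = proportional_hazard_test(cph, df, time_transform="rank")
        for name in ["smoke", "age"]:
            assert ours[name][1] == pytest.approx(
                theirs.summary.loc[name, "p"].item(), abs=0.05)
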