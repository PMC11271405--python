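import numpy as np
import pytest
from scipy import optimize
from scipy import stats as sps

from pgtflow.stats import (
    SurvivalCurve,
    chisq_prop,
    cox_fit,
    exact_binomial_ci,
    km_fit,
    logrank,
)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # events at 1, 3, 5 with censoring at 2, 4:
        # S(1) = 4/5; S(3) = 4/5 * 2/3 = 8/15; S(5) = 0
        curve = km_fit([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(0.8)
        assert curve.survival_at(3) == pytest.approx(8 / 15)
        assert curve.survival_at(5) == pytest.approx(0.0)
        assert curve.survival_at(0.5) == 1.0
        assert curve.survival_at(4.9) == pytest.approx(8 / 15)

    def test_all_censored(self):
        curve = km_fit([3, 5, 9], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(100) == 1.0
        assert curve.median() is None

    def test_single_subject_event(self):
        curve = km_fit([10], [1])
        assert curve.survival_at(10) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 200)
        curve = km_fit(t, np.ones(200, dtype=bool))
        for q in (2.0, 5.0, 12.0):
            assert curve.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_survival_non_increasing_and_risk_non_increasing(self):
        rng = np.random.default_rng(5)
        t = np.ceil(rng.exponential(20, 300))
        e = rng.random(300) < 0.6
        curve = km_fit(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all(np.diff(curve.n_at_risk) <= 0)
        assert curve.survival[0] <= 1.0

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(6)
        t = np.ceil(rng.exponential(15, 150))
        e = rng.random(150) < 0.7
        curve = km_fit(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tt in curve.event_times:
            assert curve.survival_at(tt) == pytest.approx(
                float(kmf.survival_function_at_times(tt).iloc[0])
            )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_fit([], [])

    def test_greenwood_ci_orders(self):
        rng = np.random.default_rng(7)
        t = np.ceil(rng.exponential(15, 120))
        e = rng.random(120) < 0.7
        curve = km_fit(t, e)
        s, lo, hi = curve.survival_at_ci(10)
        assert 0 <= lo <= s <= hi <= 1


class TestLogrank:
    def test_identical_groups(self):
        d = [2, 4, 6, 8, 10]
        e = [1, 1, 0, 1, 0]
        res = logrank((d, e), (d, e))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_separated_groups_vs_hand_oracle(self):
        # A events at 1,2,3; B events at 4,5,6; no censoring.
        # Independent brute-force O-E / V accumulation over event times.
        da, ea = [1, 2, 3], [1, 1, 1]
        db, eb = [4, 5, 6], [1, 1, 1]
        o_minus_e = 0.0
        var = 0.0
        all_t = [(1, "a"), (2, "a"), (3, "a"), (4, "b"), (5, "b"), (6, "b")]
        na, nb = 3, 3
        for _, grp in all_t:
            n = na + nb
            e_a = na / n  # one event at each time
            o_a = 1.0 if grp == "a" else 0.0
            o_minus_e += o_a - e_a
            var += (na * nb) / (n * n) if n > 1 else 0.0
            if grp == "a":
                na -= 1
            else:
                nb -= 1
        expected = o_minus_e**2 / var
        res = logrank((da, ea), (db, eb))
        assert res.statistic == pytest.approx(expected)
        assert res.df == 1

    def test_matches_lifelines_two_group(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(8)
        d1 = np.ceil(rng.exponential(10, 60))
        d2 = np.ceil(rng.exponential(16, 70))
        e1 = rng.random(60) < 0.8
        e2 = rng.random(70) < 0.8
        res = logrank((d1, e1), (d2, e2))
        ref = logrank_test(d1, d2, e1, e2)
        assert res.statistic == pytest.approx(ref.test_statistic)
        assert res.p_value == pytest.approx(ref.p_value)

    def test_matches_lifelines_three_group(self):
        import pandas as pd
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(9)
        ds = [np.ceil(rng.exponential(s, 50)) for s in (8, 12, 20)]
        es = [rng.random(50) < 0.75 for _ in range(3)]
        res = logrank(*zip(ds, es))
        df = pd.DataFrame(
            {
                "d": np.concatenate(ds),
                "e": np.concatenate(es),
                "g": np.repeat([0, 1, 2], 50),
            }
        )
        ref = multivariate_logrank_test(df.d, df.g, df.e)
        assert res.df == 2
        assert res.statistic == pytest.approx(ref.test_statistic)

    def test_statistic_scales_with_sample_size(self):
        rng = np.random.default_rng(10)
        d1 = np.ceil(rng.exponential(10, 100))
        d2 = np.ceil(rng.exponential(20, 100))
        e = np.ones(100, dtype=bool)
        s1 = logrank((d1, e), (d2, e)).statistic
        s2 = logrank(
            (np.concatenate([d1, d1]), np.concatenate([e, e])),
            (np.concatenate([d2, d2]), np.concatenate([e, e])),
        ).statistic
        assert s2 == pytest.approx(2 * s1, rel=0.15)

    def test_zero_subject_group_errors(self):
        with pytest.raises(ValueError, match="zero subjects"):
            logrank(([1, 2], [1, 1]), ([], []))

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            logrank(([1, 2], [0, 0]), ([3], [0]))


class TestCox:
    @staticmethod
    def _sim(seed, n=300, beta=(0.5, -0.3), censor=0.3):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, (n, len(beta))).astype(float)
        lam = 0.05 * np.exp(x @ np.asarray(beta))
        t = np.ceil(rng.exponential(1 / lam))
        e = rng.random(n) > censor
        return t, e, x

    def test_symmetric_groups_hr_one(self):
        d = np.array([5, 8, 12, 20, 30, 5, 8, 12, 20, 30], float)
        e = np.ones(10, dtype=bool)
        x = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], float).reshape(-1, 1)
        fit = cox_fit(d, e, x)
        assert fit.hazard_ratios[0] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines(self, ties):
        import pandas as pd
        from lifelines import CoxPHFitter

        t, e, x = self._sim(12)
        fit = cox_fit(t, e, x, ties=ties)
        df = pd.DataFrame({"t": t, "e": e, "x0": x[:, 0], "x1": x[:, 1]})
        # lifelines CoxPHFitter implements the Efron correction
        if ties == "efron":
            cph = CoxPHFitter().fit(df, "t", "e")
            assert fit.coefficients == pytest.approx(cph.params_.values, abs=1e-5)
            assert fit.standard_errors == pytest.approx(
                cph.standard_errors_.values, abs=1e-5
            )
        else:
            assert fit.converged

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(10, 100)  # continuous, ties have probability 0
        e = rng.random(100) < 0.8
        x = rng.integers(0, 2, (100, 1)).astype(float)
        fe = cox_fit(t, e, x, ties="efron")
        fb = cox_fit(t, e, x, ties="breslow")
        assert fe.coefficients == pytest.approx(fb.coefficients, abs=1e-8)

    def test_recovers_known_hr(self):
        # two-arm exponential data with true HR 0.43
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            x = rng.integers(0, 2, (n, 1)).astype(float)
            lam = 0.02 * np.exp(np.log(0.43) * x[:, 0])
            t = rng.exponential(1 / lam)
            e = rng.random(n) < 0.9
            fit = cox_fit(t, e, x)
            if abs(fit.hazard_ratios[0] - 0.43) < 0.07:
                hits += 1
        assert hits >= 9

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3], [1, 1, 1], np.ones((3, 1)))

    def test_separation_flagged(self):
        # perfect separation: all events in one arm before the other starts
        t = np.array([1, 2, 3, 10, 11, 12], float)
        e = np.ones(6, dtype=bool)
        x = np.array([1, 1, 1, 0, 0, 0], float).reshape(-1, 1)
        fit = cox_fit(t, e, x)
        assert fit.separation_flag or not fit.converged

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit([1, 2], [0, 0], np.array([[0.0], [1.0]]))


class TestChisq:
    def test_flat_table(self):
        res = chisq_prop([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_oracle(self):
        table = [[53, 44], [10, 33]]
        # brute-force expected counts
        obs = np.asarray(table, float)
        total = obs.sum()
        stat = 0.0
        for i in range(2):
            for j in range(2):
                exp = obs[i].sum() * obs[:, j].sum() / total
                stat += (obs[i, j] - exp) ** 2 / exp
        res = chisq_prop(table)
        assert res.statistic == pytest.approx(stat)
        ref = sps.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_2x3_df(self):
        res = chisq_prop([[5, 10, 15], [10, 10, 10]])
        assert res.df == 2

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="zero marginal"):
            chisq_prop([[0, 0], [5, 10]])


class TestExactBinomialCI:
    def test_boundaries(self):
        lo, hi = exact_binomial_ci(0, 10)
        assert lo == 0.0
        lo, hi = exact_binomial_ci(10, 10)
        assert hi == 1.0

    def test_13_of_31_rounds_to_25_61(self):
        lo, hi = exact_binomial_ci(13, 31)
        assert round(100 * lo) == 25
        assert round(100 * hi) == 61

    def test_matches_tail_sum_inversion_oracle(self):
        # direct root-finding on the binomial tail sums
        k, n, alpha = 13, 31, 0.05
        lo_oracle = optimize.brentq(
            lambda p: 1 - sps.binom.cdf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12
        )
        hi_oracle = optimize.brentq(
            lambda p: sps.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12
        )
        lo, hi = exact_binomial_ci(k, n)
        assert lo == pytest.approx(lo_oracle, abs=1e-9)
        assert hi == pytest.approx(hi_oracle, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_ci(-1, 4)
        with pytest.raises(ValueError):
            exact_binomial_ci(1, 4, level=1.5)

    def test_coverage_at_least_nominal(self):
        # exhaustive coverage enumeration for n <= 30
        for n in range(1, 31):
            ks = np.arange(n + 1)
            los, his = zip(*(exact_binomial_ci(int(k), n) for k in ks))
            los, his = np.array(los), np.array(his)
            for p in np.arange(0.1, 0.95, 0.1):
                pmf = sps.binom.pmf(ks, n, p)
                covered = pmf[(los <= p) & (p <= his)].sum()
                assert covered >= 0.95 - 1e-9, (n, p)


def test_testresult_p_monotone_in_statistic():
    ps = [float(sps.chi2.sf(s, 1)) for s in (0.5, 1.0, 2.0, 4.0)]
    assert ps == sorted(ps, reverse=True)


def test_survival_curve_median():
    curve = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
    assert curve.median() == 2
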