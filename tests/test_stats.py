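import numpy as np
import pandas as pd
import pytest
import scipy.stats

from owclust.datatypes import SurvivalData
from owclust.stats import (
    chi_square_test,
    fit_cox_multivariable,
    km_logrank,
    kruskal_wallis,
    truncate_survival,
)


class TestChiSquare:
    def test_observed_equals_expected_gives_zero(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_by_two_matches_scipy_with_correction(self):
        table = [[35, 44], [16, 67]]
        ours = chi_square_test(table)
        ref = scipy.stats.chi2_contingency(np.asarray(table), correction=True)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.df == 1
        assert ours.correction_applied

    def test_larger_table_uncorrected_matches_scipy(self):
        table = [[12, 7, 9], [5, 14, 11]]
        ours = chi_square_test(table)
        ref = scipy.stats.chi2_contingency(np.asarray(table), correction=False)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.df == 2
        assert not ours.correction_applied

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test([[0, 0], [5, 7]])

    def test_continuity_flag_forces_correction_off(self):
        table = [[35, 44], [16, 67]]
        corrected = chi_square_test(table, continuity=True)
        plain = chi_square_test(table, continuity=False)
        assert plain.statistic > corrected.statistic


class TestKruskalWallis:
    def test_null_p_values_uniform(self):
        hits = 0
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.normal(size=1000)
            g = rng.integers(0, 2, size=1000)
            if kruskal_wallis(x, g).p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / 200 <= 0.09

    def test_hand_computed_rank_formula(self):
        values = [1, 2, 3, 10, 11, 12]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = kruskal_wallis(values, groups)
        # ranks 1..6, R_a = 6, R_b = 15: H = 12/(6*7) * (36/3 + 225/3) - 3*7
        assert res.statistic == pytest.approx(3.857142857, abs=1e-9)
        assert res.df == 1

    def test_all_values_tied_gives_zero(self):
        res = kruskal_wallis([5.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


def _surv(time, event):
    return SurvivalData(np.asarray(time, float), np.asarray(event, int),
                        [f"S{i}" for i in range(len(time))])


class TestKMLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [3.0, 5.0, 8.0, 12.0]
        e = [1, 0, 1, 1]
        surv = _surv(t + t, e + e)
        km, lr = km_logrank(surv, ["A"] * 4 + ["B"] * 4)
        assert lr.statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_computed_logrank(self):
        # times 1,2,3,4 all events, groups A,A,B,B: accumulate O-E and
        # hypergeometric variance at each event time by hand
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 1])
        groups = np.array(["A", "A", "B", "B"])
        at_risk = [(2, 4), (1, 3), (0, 2), (0, 1)]  # (A at risk, total) per time
        deaths_a = [1, 1, 0, 0]
        U = sum(d - na / n for (na, n), d in zip(at_risk, deaths_a))
        # hypergeometric variance with one death per time: na*nb*(n-1)/(n^2*(n-1))
        V = sum(na * (n - na) * (n - 1) / (n**2 * (n - 1))
                for (na, n) in at_risk if n > 1)
        _, lr = km_logrank(surv, groups, cutoff_months=None)
        assert lr.statistic == pytest.approx(U**2 / V, abs=1e-10)

    def test_hazard_ratio_three_detected(self):
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = np.repeat([0, 1], 150)
            t = rng.exponential(np.where(g == 0, 30.0, 10.0)) + 1e-3
            _, lr = km_logrank(_surv(t, np.ones(300)), g)
            detected += lr.p_value < 0.01
        assert detected >= 19

    def test_cutoff_recodes_late_events_as_censored(self):
        surv = _surv([10, 50, 70, 90], [1, 1, 1, 1])
        out = truncate_survival(surv, 60.0)
        np.testing.assert_array_equal(out.time, [10, 50, 60, 60])
        np.testing.assert_array_equal(out.event, [1, 1, 0, 0])
        assert out.n_events <= surv.n_events

    def test_km_curves_start_at_one_and_decrease(self, rng):
        t = rng.exponential(20, size=80) + 0.01
        e = rng.integers(0, 2, size=80)
        e[0] = 1
        g = rng.integers(0, 2, size=80)
        km, _ = km_logrank(_surv(t, e), g)
        for grp in km.groups:
            s = km.survival[grp]
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            km_logrank(_surv([5, 6, 7, 8], [0, 0, 0, 0]), ["A", "A", "B", "B"])


class TestCoxMultivariable:
    def _simulate(self, rng, n, betas, censor_scale=None):
        p = len(betas)
        X = rng.standard_normal((n, p))
        rate = np.exp(X @ np.asarray(betas)) / 10.0
        t = rng.exponential(1.0 / rate)
        e = np.ones(n, dtype=int)
        if censor_scale:
            c = rng.exponential(censor_scale, n)
            e = (t <= c).astype(int)
            t = np.minimum(t, c)
        surv = _surv(t + 1e-9, e)
        cov = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
        return surv, cov

    def test_parameter_recovery_and_identities(self):
        rng = np.random.default_rng(1)
        surv, cov = self._simulate(rng, 2000, [0.9])
        res = fit_cox_multivariable(surv, cov)
        b = res.table.loc["x0"]
        assert 0.8 <= b["B"] <= 1.0
        assert b["HR"] == pytest.approx(np.exp(b["B"]), rel=1e-12)
        assert b["CI95_low"] == pytest.approx(np.exp(b["B"] - 1.96 * b["SE"]), rel=1e-12)
        assert b["CI95_high"] == pytest.approx(np.exp(b["B"] + 1.96 * b["SE"]), rel=1e-12)
        assert b["Wald"] == pytest.approx((b["B"] / b["SE"]) ** 2, rel=1e-12)

    def test_null_covariate_hazard_ratio_near_one(self):
        rng = np.random.default_rng(2)
        surv, cov = self._simulate(rng, 2000, [0.0])
        res = fit_cox_multivariable(surv, cov)
        assert 0.9 <= res.table.loc["x0", "HR"] <= 1.1

    def test_epv_reported(self):
        rng = np.random.default_rng(3)
        surv, cov = self._simulate(rng, 200, [0.5, 0.0, 0.0, 0.0], censor_scale=8.0)
        res = fit_cox_multivariable(surv, cov)
        assert res.epv == pytest.approx(surv.n_events / 4)
        assert np.isfinite(res.schoenfeld_global_p)
        assert set(res.table["schoenfeld_p"].index) == set(cov.columns)

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(4)
        surv, cov = self._simulate(rng, 50, [0.5])
        cov["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox_multivariable(surv, cov)

    def test_more_covariates_than_events_rejected(self):
        rng = np.random.default_rng(5)
        surv, cov = self._simulate(rng, 30, [0.0, 0.0])
        surv.event[:] = 0
        surv.event[0] = 1
        with pytest.raises(ValueError, match="events"):
            fit_cox_multivariable(surv, cov)
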