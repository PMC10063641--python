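"""Survival machinery: product-limit curves, log-rank, Cox/Breslow,
concordance, cross-validation, LRT, stratification, and associations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltarad.survival import (confusion_metrics, covariate_association,
                               cv_cstatistic, fit_cox, harrell_c,
                               harrell_c_bruteforce, km_estimate,
                               logrank_test, lr_test, risk_stratify)


def survival_frame(rng, n=200, log_hr=1.0, p_group=0.5, base=0.1,
                   censor_max=10.0):
    g = rng.binomial(1, p_group, n)
    lam = base * np.exp(log_hr * g)
    T = rng.exponential(1 / lam)
    C = rng.uniform(0, censor_max, n)
    return pd.DataFrame({"grp": g.astype(float),
                         "noise": rng.normal(size=n),
                         "rfs_years": np.minimum(T, C),
                         "event": (T <= C).astype(int)})


class TestKm:
    def test_hand_product_limit(self):
        curves = km_estimate([1, 2, 3], [1, 1, 0])
        c = curves[0].set_index("time")["survival"]
        assert c.loc[1.0] == pytest.approx(2 / 3)
        assert c.loc[2.0] == pytest.approx(1 / 3)
        assert c.loc[3.0] == pytest.approx(1 / 3)

    def test_all_censored_flat_curve(self):
        curves = km_estimate([1, 2, 3], [0, 0, 0])
        assert (curves[0]["survival"] == 1.0).all()

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 40)
        e = rng.binomial(1, 0.7, 40)
        curves = km_estimate(t, e)
        s = curves[0]["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert s[0] == 1.0

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4]
        e = [1, 0, 1, 1]
        stat, p = logrank_test(t + t, e + e, [0] * 4 + [1] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulation_oracle(self):
        """Observed-minus-expected tabulation over the six event times."""
        times = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        events = np.ones(6, dtype=int)
        groups = np.array([0, 0, 0, 1, 1, 1])
        # hand tabulation of the standard log-rank statistic
        o_minus_e = 0.0
        var = 0.0
        for t in times:
            at_risk = times >= t
            n = at_risk.sum()
            n0 = (at_risk & (groups == 0)).sum()
            d = ((times == t) & (events == 1)).sum()
            d0 = ((times == t) & (events == 1) & (groups == 0)).sum()
            o_minus_e += d0 - d * n0 / n
            if n > 1:
                var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
        expected_stat = o_minus_e ** 2 / var
        stat, _ = logrank_test(times, events, groups)
        assert stat == pytest.approx(expected_stat, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_matches_breslow_reference(self):
        """Coefficients agree with scikit-survival's Breslow-tie Cox."""
        sksurv = pytest.importorskip("sksurv.linear_model")
        rng = np.random.default_rng(1)
        df = survival_frame(rng, n=250)
        fit = fit_cox(df, ["grp", "noise"])
        y = np.array([(bool(e), t) for e, t in
                      zip(df["event"], df["rfs_years"])],
                     dtype=[("e", bool), ("t", float)])
        ref = sksurv.CoxPHSurvivalAnalysis(ties="breslow").fit(
            df[["grp", "noise"]].to_numpy(), y)
        np.testing.assert_allclose(fit.coef, ref.coef_, atol=1e-6)

    def test_duplicating_subjects_preserves_coefficients(self):
        rng = np.random.default_rng(2)
        df = survival_frame(rng, n=120)
        fit1 = fit_cox(df, ["grp", "noise"])
        fit2 = fit_cox(pd.concat([df, df], ignore_index=True),
                       ["grp", "noise"])
        np.testing.assert_allclose(fit1.coef, fit2.coef, atol=1e-7)

    def test_collinear_rejected_naming_pair(self):
        rng = np.random.default_rng(3)
        df = survival_frame(rng, n=50)
        df["copy"] = df["grp"]
        with pytest.raises(ValueError, match="grp.*copy"):
            fit_cox(df, ["grp", "copy"])

    def test_planted_null_coefficient_small(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(30):
            df = survival_frame(rng, n=500, log_hr=0.0)
            fit = fit_cox(df, ["noise"])
            hits += abs(fit.coef[0]) < 0.2
        assert hits >= 28  # ~95% of null fits are near zero

    def test_few_events_warns(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                           "rfs_years": [1, 2, 3, 4.0],
                           "event": [1, 0, 0, 0]})
        with pytest.warns(UserWarning, match="events"):
            fit_cox(df, ["x"])


class TestHarrellC:
    def test_perfect_ranking(self):
        assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_constant_predictor_half(self):
        assert harrell_c([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_no_usable_pairs_nan(self):
        assert np.isnan(harrell_c([1, 2], [1, 2], [0, 0]))

    @given(st.integers(0, 1000))
    @settings(max_examples=25)
    def test_vectorized_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        lp = rng.normal(size=n).round(1)  # rounding forces predictor ties
        t = rng.exponential(1, n).round(2)
        e = rng.binomial(1, 0.6, n)
        c1 = harrell_c(lp, t, e)
        c2 = harrell_c_bruteforce(lp, t, e)
        if np.isnan(c1):
            assert np.isnan(c2)
        else:
            assert c1 == c2


class TestCv:
    def test_same_seed_identical(self):
        rng = np.random.default_rng(5)
        df = survival_frame(rng, n=120)
        r1 = cv_cstatistic(df, ["grp"], replicates=5, seed=9)
        r2 = cv_cstatistic(df, ["grp"], replicates=5, seed=9)
        np.testing.assert_array_equal(r1.c_per_replicate, r2.c_per_replicate)
        assert r1.mean_c == r2.mean_c

    def test_result_bookkeeping(self):
        rng = np.random.default_rng(6)
        df = survival_frame(rng, n=100)
        res = cv_cstatistic(df, ["grp"], replicates=8, seed=1)
        assert res.c_per_replicate.shape == (8,)
        assert min(res.c_per_replicate) <= res.mean_c \
            <= max(res.c_per_replicate)
        lo, hi = res.percentile_interval
        assert lo <= res.mean_c <= hi


class TestLrt:
    def test_nested_guard(self):
        rng = np.random.default_rng(7)
        df = survival_frame(rng, n=100)
        full = fit_cox(df, ["grp", "noise"])
        other = fit_cox(df, ["noise"])
        stat, dof, p = lr_test(other, full)
        assert dof == 1 and stat >= 0 and 0 <= p <= 1
        with pytest.raises(ValueError, match="nested"):
            lr_test(full, other)

    def test_duplicate_covariate_guarded_upstream(self):
        rng = np.random.default_rng(8)
        df = survival_frame(rng, n=60)
        df["copy"] = df["grp"]
        with pytest.raises(ValueError, match="collinear"):
            fit_cox(df, ["grp", "copy"])

    def test_prognostic_covariate_power(self):
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(25):
            df = survival_frame(rng, n=300, log_hr=1.5)
            nested = fit_cox(df, ["noise"])
            full = fit_cox(df, ["noise", "grp"])
            _, _, p = lr_test(nested, full)
            rejections += p < 0.05
        assert rejections >= 23  # >= 90% power


class TestRiskStratify:
    def test_dot_product_arithmetic(self):
        from deltarad.survival import CoxFit
        fit = CoxFit(covariates=["x1", "x2"], coef=np.array([1.0, 0.0]),
                     log_likelihood=0.0, log_likelihood_null=0.0,
                     c_statistic=0.5, linear_predictor=pd.Series(dtype=float),
                     n=1, n_events=1)
        table = pd.DataFrame({"x1": [2.0], "x2": [9.0]})
        risk, _ = risk_stratify(fit, pd.concat(
            [table, table + 1], ignore_index=True))
        assert risk.iloc[0] == pytest.approx(2.0)

    def test_median_split_counts(self):
        from deltarad.survival import CoxFit
        fit = CoxFit(covariates=["x"], coef=np.array([1.0]),
                     log_likelihood=0.0, log_likelihood_null=0.0,
                     c_statistic=0.5, linear_predictor=pd.Series(dtype=float),
                     n=1, n_events=1)
        table = pd.DataFrame({"x": np.arange(10, dtype=float)})
        _, labels = risk_stratify(fit, table)
        assert (labels == "high").sum() == 5

    def test_all_equal_refused(self):
        from deltarad.survival import CoxFit
        fit = CoxFit(covariates=["x"], coef=np.array([1.0]),
                     log_likelihood=0.0, log_likelihood_null=0.0,
                     c_statistic=0.5, linear_predictor=pd.Series(dtype=float),
                     n=1, n_events=1)
        with pytest.raises(ValueError, match="refused"):
            risk_stratify(fit, pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


class TestConfusion:
    def test_count_arithmetic(self):
        pred = np.array([1] * 40 + [0] * 60, dtype=bool)
        ev = np.zeros(100, dtype=int)
        ev[:20] = 1          # 20 events among predicted positive
        ev[40:48] = 1        # 8 events among predicted negative
        m = confusion_metrics(pred, ev)
        assert m["ppv"] == pytest.approx(0.5)
        assert m["npv"] == pytest.approx(52 / 60)

    def test_perfect_prediction(self):
        ev = np.array([1, 1, 0, 0])
        m = confusion_metrics(ev.astype(bool), ev)
        assert m["ppv"] == 1.0 and m["npv"] == 1.0

    def test_swapped_convention_recount(self):
        rng = np.random.default_rng(0)
        pred = rng.random(50) > 0.5
        ev = rng.binomial(1, 0.4, 50)
        m = confusion_metrics(pred, ev)
        sw = confusion_metrics(~pred, ev)
        assert sw["tp"] == m["fn"] and sw["fp"] == m["tn"]
        assert sw["ppv"] == pytest.approx(
            m["fn"] / (m["fn"] + m["tn"]) if m["fn"] + m["tn"] else np.nan)

    def test_empty_positive_set_undefined(self):
        m = confusion_metrics(np.zeros(5, dtype=bool), np.ones(5, dtype=int))
        assert np.isnan(m["ppv"])


class TestAssociations:
    def test_bonferroni_threshold_seven_tests(self):
        rng = np.random.default_rng(1)
        n = 80
        phen = rng.integers(1, 3, n)
        table = pd.DataFrame({f"c{i}": rng.normal(size=n) for i in range(4)})
        for i in range(3):
            table[f"b{i}"] = rng.binomial(1, 0.5, n)
        types = {f"c{i}": "continuous" for i in range(4)}
        types.update({f"b{i}": "categorical" for i in range(3)})
        res = covariate_association(table, phen, types)
        assert res.attrs["n_tests"] == 7
        assert res.attrs["alpha_bonferroni"] == pytest.approx(0.00714,
                                                              abs=5e-5)

    def test_chi_square_hand_value(self):
        # 2x2 table (10,0 / 0,10): chi-square 20 without continuity
        phen = np.array([1] * 10 + [2] * 10)
        table = pd.DataFrame({"flag": [1] * 10 + [0] * 10})
        res = covariate_association(table, phen, {"flag": "categorical"})
        assert res.loc["flag", "stat"] == pytest.approx(20.0)

    def test_single_level_skipped(self):
        phen = np.array([1, 1, 2, 2])
        table = pd.DataFrame({"const": [1, 1, 1, 1],
                              "x": [0.1, 0.4, 0.2, 0.9]})
        res = covariate_association(table, phen,
                                    {"const": "categorical",
                                     "x": "continuous"})
        assert res.loc["const", "note"] == "skipped:single-level"
        assert res.attrs["n_tests"] == 1

    def test_permuted_labels_uniform_p(self):
        """Permutation-null calibration: raw p-values are roughly uniform
        under label exchange."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        ps = []
        for _ in range(200):
            phen = rng.permutation([1] * 50 + [2] * 50)
            res = covariate_association(pd.DataFrame({"x": x}), phen,
                                        {"x": "continuous"})
            ps.append(res.loc["x", "p"])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01
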