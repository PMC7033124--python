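import numpy as np
import pandas as pd
import pytest

from strandcoop.survival import (
    compare_signatures,
    cox_fit,
    fdr_over_cancers,
    kaplan_meier,
    logrank_test,
    quartile_stratify,
    signature_score,
    truncate_followup,
)


class TestSignature:
    def _expr(self, values):
        return pd.DataFrame(
            values,
            index=["m145-5p", "m145-3p", "m30a-5p", "m30a-3p"],
            columns=["s1", "s2"],
        )

    def test_constant_strands_give_constant_score(self):
        expr = self._expr(np.full((4, 2), 7.0))
        score = signature_score(expr, expr.index, log_scale=False)
        assert np.allclose(score, 7.0)

    def test_strand_order_irrelevant_and_mean_correct(self):
        expr = self._expr(np.array([[1.0, 1], [2, 2], [3, 3], [4, 4]]))
        a = signature_score(expr, list(expr.index), log_scale=False)
        b = signature_score(expr, list(expr.index)[::-1], log_scale=False)
        assert np.allclose(a, 2.5) and np.allclose(a, b)

    def test_missing_strand_rejected(self):
        expr = self._expr(np.ones((4, 2)))
        with pytest.raises(KeyError):
            signature_score(expr, ["m145-5p", "absent"])


class TestQuartiles:
    def test_eight_distinct_scores_split_in_twos(self):
        s = pd.Series(np.arange(8.0), index=[f"p{i}" for i in range(8)])
        labels = quartile_stratify(s)
        assert labels.value_counts().to_dict() == {f"Q{i}": 2 for i in range(1, 5)}
        assert set(labels[s < 2]) == {"Q1"}
        assert set(labels[s >= 6]) == {"Q4"}

    def test_ten_patients_near_equal_and_deterministic(self):
        s = pd.Series(np.arange(10.0), index=[f"p{i}" for i in range(10)])
        sizes = sorted(quartile_stratify(s).value_counts())
        assert sizes == [2, 2, 3, 3]
        pd.testing.assert_series_equal(quartile_stratify(s), quartile_stratify(s))

    def test_all_tied_assigned_by_id_order(self):
        s = pd.Series(1.0, index=[f"p{i}" for i in range(8)])
        with pytest.warns(UserWarning):
            labels = quartile_stratify(s)
        assert labels.loc["p0"] == "Q1" and labels.loc["p7"] == "Q4"


class TestKaplanMeier:
    def test_hand_computed_no_censoring(self):
        km, median = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km["survival"], [0.75, 0.5, 0.25, 0.0])
        assert median == 2.0

    def test_everyone_censored_keeps_survival_one(self):
        km, median = kaplan_meier([5, 6, 7], [0, 0, 0])
        assert km.empty and np.isnan(median)

    def test_matches_lifelines_on_random_instances(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(100)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            time = rng.exponential(10, n).round(1) + 0.1
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                continue
            km, _ = kaplan_meier(time, event)
            kmf = KaplanMeierFitter().fit(time, event)
            for _, row in km.iterrows():
                ref = float(kmf.survival_function_at_times(row["time"]).iloc[0])
                assert row["survival"] == pytest.approx(ref, abs=1e-10)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_tiny_instance_matches_hand_counts(self):
        # A: deaths at 1, 2; B: deaths at 3, 4; no censoring
        # t=1: n=4, nA=2, d=1 -> e=0.5, v=(2/4)(2/4)(3/3)=0.25
        # t=2: n=3, nA=1, d=1 -> e=1/3, v=(1/3)(2/3)(1)=2/9
        # t=3: n=2, nA=0, d=1 -> e=0, v=0... nA=0 so terms vanish
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        o_minus_e = (1 - 0.5) + (1 - 1 / 3)
        var = 0.25 + 2 / 9
        assert chi2 == pytest.approx(o_minus_e**2 / var)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(101)
        for _ in range(30):
            n = 40
            ta = rng.exponential(10, n).round(1) + 0.1
            tb = rng.exponential(14, n).round(1) + 0.1
            ea = rng.integers(0, 2, n)
            eb = rng.integers(0, 2, n)
            if ea.sum() == 0 or eb.sum() == 0:
                continue
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
            assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_zero_variance_gives_p_one(self):
        assert logrank_test([1], [0], [2], [0]) == (0.0, 1.0)


class TestTruncation:
    def test_truncation_rules(self):
        clin = pd.DataFrame(
            {"time_months": [150.0, 100.0, 121.0], "event": [1, 1, 0]},
            index=["a", "b", "c"],
        )
        out = truncate_followup(clin, horizon=120)
        assert out.loc["a", "time_months"] == 120 and out.loc["a", "event"] == 0
        assert out.loc["b", "time_months"] == 100 and out.loc["b", "event"] == 1
        assert out["event"].sum() <= clin["event"].sum()


def grid_search_cox_beta(x, time, event):
    """Independent oracle: maximize the Breslow partial likelihood on a
    dense beta grid (single covariate)."""
    def pl(beta):
        ll = 0.0
        for t in np.unique(time[event == 1]):
            at_risk = time >= t
            deaths = (time == t) & (event == 1)
            d = deaths.sum()
            ll += beta * x[deaths].sum() - d * np.log(np.exp(beta * x[at_risk]).sum())
        return ll

    grid = np.linspace(-4, 4, 4001)
    return grid[np.argmax([pl(b) for b in grid])]


class TestCox:
    def test_newton_matches_grid_search_oracle(self):
        rng = np.random.default_rng(102)
        for _ in range(5):
            n = 80
            x = rng.integers(0, 2, n).astype(float)
            lam = 0.05 * 0.4**x
            time = rng.exponential(1 / lam).round(2) + 0.01
            event = np.ones(n, dtype=int)
            res = cox_fit(pd.DataFrame({"x": x}), time, event)[0]
            beta_ref = grid_search_cox_beta(x, time, event)
            assert res.coef == pytest.approx(beta_ref, abs=2e-3)

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(103)
        n = 120
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        lam = 0.03 * np.exp(0.5 * x1 - 0.8 * x2)
        time = rng.exponential(1 / lam)  # continuous -> no ties
        event = (rng.uniform(size=n) < 0.8).astype(int)
        res = cox_fit(pd.DataFrame({"x1": x1, "x2": x2}), time, event)
        df = pd.DataFrame({"T": time, "E": event, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, "T", "E")
        for r in res:
            assert r.coef == pytest.approx(cph.params_[r.covariate], abs=1e-5)
            assert r.se == pytest.approx(cph.standard_errors_[r.covariate], abs=1e-5)

    def test_null_covariate_wald_p_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(104)
        ps = []
        for _ in range(200):
            n = 60
            x = rng.normal(size=n)
            time = rng.exponential(10, n)
            event = np.ones(n, dtype=int)
            ps.append(cox_fit(pd.DataFrame({"x": x}), time, event)[0].wald_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_monotone_likelihood_flagged(self):
        # perfect separation: all events in one group, first
        time = np.array([1.0, 2, 3, 10, 11, 12])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1, 1, 0, 0, 0])
        res = cox_fit(pd.DataFrame({"x": x}), time, event)[0]
        assert not res.converged


class TestCompareSignatures:
    def test_stronger_reference_detected(self):
        variants = {
            "four": {f"C{i}": 1e-6 for i in range(6)},
            "single": {f"C{i}": 0.3 for i in range(6)},
            "pair": {f"C{i}": 0.2 for i in range(6)},
        }
        assert compare_signatures(variants, "four") < 0.01

    def test_identical_variants_not_significant(self):
        variants = {
            "four": {f"C{i}": 0.1 for i in range(5)},
            "other": {f"C{i}": 0.1 for i in range(5)},
        }
        assert compare_signatures(variants, "four") > 0.4

    def test_too_few_cancers_rejected(self):
        with pytest.raises(ValueError):
            compare_signatures({"four": {"C1": 0.1}, "o": {"C1": 0.2}}, "four")


def test_fdr_over_cancers_is_bh():
    from strandcoop.diffexpr import bh_adjust

    ps = {"C1": 0.01, "C2": 0.04, "C3": 0.8}
    out = fdr_over_cancers(ps)
    assert np.allclose(
        [out[c] for c in sorted(ps)], bh_adjust([ps[c] for c in sorted(ps)])
    )
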