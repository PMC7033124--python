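import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from strandcoop.datatypes import ExpressionStudy
from strandcoop.diffexpr import (
    bh_adjust,
    call_differential,
    estimate_common_dispersion,
    filter_expressed,
    nb_exact_test,
    spearman,
    spearman_pairs,
    tmm_factors,
)

# edgeR 4.0.16 calcNormFactors(method="TMM") on the deterministic fixture
# regenerated below (independent reference implementation, frozen values)
EDGER_TMM = [
    1.0025133636, 1.0455227273, 1.0215049575,
    0.9883574479, 0.9567264528, 0.9877204637,
]


def _tmm_fixture():
    rng = np.random.default_rng(42)
    mu = np.exp(rng.normal(np.log(100), 1, size=300))
    lib = np.array([1.0, 1.6, 0.7, 1.2, 2.0, 0.9])
    counts = rng.negative_binomial(5, 5 / (5 + mu[:, None] * lib[None, :]))
    return pd.DataFrame(
        counts, index=[f"g{i}" for i in range(300)],
        columns=[f"s{i}" for i in range(6)],
    )


class TestFilterExpressed:
    def test_half_expressed_feature_is_kept(self):
        counts = pd.DataFrame(
            [[0, 0, 2, 3], [0, 0, 0, 0], [5, 5, 5, 5]],
            index=["half", "zero", "full"],
            columns=list("abcd"),
        )
        study = ExpressionStudy(
            cancer_type="T",
            raw_counts=counts,
            normalized=counts.astype(float),
            feature_kind="miRNA",
            sample_groups=pd.Series(
                ["tumor", "tumor", "normal", "normal"], index=counts.columns
            ),
        )
        kept = filter_expressed(study, min_value=1, min_fraction=0.5)
        assert list(kept.features) == ["half", "full"]
        assert filter_expressed(study, min_fraction=0).features.equals(
            study.features
        )


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(tmm_factors(df), [1.0, 1.0])

    def test_scaled_column_absorbed_into_library_size(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(100, size=500)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        f = tmm_factors(df)
        assert np.allclose(f, [1.0, 1.0], atol=1e-6)
        eff = df.sum(axis=0) * f
        assert eff["b"] / eff["a"] == pytest.approx(2.0, rel=1e-6)

    def test_matches_reference_implementation(self):
        f = tmm_factors(_tmm_fixture())
        assert np.allclose(f.to_numpy(), EDGER_TMM, atol=1e-6)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            tmm_factors(df)


class TestCommonDispersion:
    def _groups(self, n):
        cols = [f"s{i}" for i in range(2 * n)]
        return cols, pd.Series(["tumor"] * n + ["normal"] * n, index=cols)

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(5)
        mu = np.exp(rng.normal(np.log(150), 1, size=2000))
        cols, groups = self._groups(10)
        counts = pd.DataFrame(rng.poisson(mu[:, None], size=(2000, 20)), columns=cols)
        assert estimate_common_dispersion(counts, groups) < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(6)
        phi, r = 0.2, 5.0
        mu = np.exp(rng.normal(np.log(150), 1, size=2000))
        cols, groups = self._groups(10)
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 20)),
            columns=cols,
        )
        assert 0.15 <= estimate_common_dispersion(counts, groups) <= 0.25

    def test_degenerate_equal_counts_give_zero(self):
        cols, groups = self._groups(3)
        counts = pd.DataFrame(np.full((5, 6), 7), columns=cols)
        assert estimate_common_dispersion(counts, groups) == 0.0


def _binom_exact_p(z1, z, p0):
    """Independent oracle: two-sided exact binomial (sum of outcomes at
    most as probable as the observed one)."""
    pmf = stats.binom.pmf(np.arange(z + 1), z, p0)
    return min(1.0, pmf[pmf <= pmf[z1] * (1 + 1e-12)].sum())


class TestExactTest:
    def _study(self, counts):
        n = counts.shape[1] // 2
        cols = [f"t{i}" for i in range(n)] + [f"n{i}" for i in range(n)]
        df = pd.DataFrame(counts, columns=cols)
        groups = pd.Series(["tumor"] * n + ["normal"] * n, index=cols)
        return df, groups, pd.Series(1.0, index=cols)

    def test_symmetric_split_gives_p_one(self):
        # one feature split 5|5 plus a balancing feature for equal libraries
        df, groups, f = self._study(np.array([[5, 5], [95, 95]]))
        p = nb_exact_test(df, groups, f, phi=0.0)
        assert p.iloc[0] == pytest.approx(1.0)

    def test_extreme_split_matches_closed_form(self):
        df, groups, f = self._study(np.array([[10, 0], [90, 100]]))
        p = nb_exact_test(df, groups, f, phi=0.0)
        assert p.iloc[0] == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_poisson_limit_matches_binomial_oracle(self):
        rng = np.random.default_rng(11)
        raw = rng.poisson(50, size=(100, 8))
        # balance column sums so library equalization is the identity
        filler = raw.sum(axis=0).max() - raw.sum(axis=0)
        counts = np.vstack([raw, filler])
        df, groups, f = self._study(counts)
        p = nb_exact_test(df, groups, f, phi=0.0)
        for i in range(100):
            z1 = int(raw[i, :4].sum())
            z = int(raw[i].sum())
            assert p.iloc[i] == pytest.approx(
                _binom_exact_p(z1, z, 0.5), abs=1e-10
            )

    def test_group_swap_leaves_p_invariant(self):
        rng = np.random.default_rng(13)
        counts = rng.poisson(40, size=(30, 6))
        df, groups, f = self._study(counts)
        swapped = groups.map({"tumor": "normal", "normal": "tumor"})
        p1 = nb_exact_test(df, groups, f, phi=0.1)
        p2 = nb_exact_test(df, swapped, f, phi=0.1)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_zero_total_gives_p_one(self):
        df, groups, f = self._study(np.array([[0, 0], [10, 10]]))
        assert nb_exact_test(df, groups, f, phi=0.0).iloc[0] == 1.0


class TestBhAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("p", [[0.2], [0.5, 0.5, 0.5]])
    def test_degenerate_inputs_unchanged(self, p):
        assert np.allclose(bh_adjust(p), p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_order_free(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1 + 1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        assert np.allclose(np.asarray(bh_adjust(np.asarray(ps)[perm]))[np.argsort(perm)], adj)


class TestCalls:
    @pytest.mark.parametrize(
        "lfc,adj_p,thr,expected",
        [
            (0.7, 0.01, 1.5, "up"),       # 0.7 > log2(1.5)
            (2.0, 0.2, 1.5, "ns"),         # not significant
            (-1.1, 0.001, 2.0, "down"),    # beyond the 2-fold cut
            (0.5, 0.01, 1.5, "ns"),        # below the 1.5-fold cut
        ],
    )
    def test_threshold_rules(self, lfc, adj_p, thr, expected):
        assert call_differential([lfc], [adj_p], thr)[0] == expected

    def test_sign_mirror(self):
        rng = np.random.default_rng(2)
        lfc = rng.normal(0, 2, 50)
        adj = rng.uniform(0, 0.2, 50)
        fwd = call_differential(lfc, adj, 1.5)
        rev = call_differential(-lfc, adj, 1.5)
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert [flip[c] for c in fwd] == list(rev)


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_exact_small_sample_matches_brute_force(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        res = spearman(x, y)
        rx = stats.rankdata(x)
        null = [
            np.corrcoef(rx, perm)[0, 1]
            for perm in itertools.permutations(stats.rankdata(y))
        ]
        expect = np.mean(np.abs(null) >= abs(res.rho) - 1e-12)
        assert res.p_value == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_flagged(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert not res.valid and math.isnan(res.rho)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 25))
        y = rng.normal(size=(10, 25))
        rho, p = spearman_pairs(x, y)
        for i in range(10):
            ref = stats.spearmanr(x[i], y[i])
            assert rho[i] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[i] == pytest.approx(ref.pvalue, rel=1e-6)
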