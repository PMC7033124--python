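import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strandcoop.enrichment import (
    RankedList,
    enrichment_score,
    gsea_significance,
    hypergeom_ora,
    ssgsea_score,
)


def naive_es(genes, metric, gene_set, exponent):
    """Independent O(N) running-sum oracle for the weighted KS statistic."""
    in_set = np.array([g in gene_set for g in genes])
    w = np.abs(metric) ** exponent
    w = np.where(in_set, w, 0.0)
    if w.sum() == 0:
        w = in_set.astype(float)
    n_miss = len(genes) - in_set.sum()
    running, best = 0.0, 0.0
    for i in range(len(genes)):
        if in_set[i]:
            running += w[i] / w.sum()
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best) + 1e-15:
            best = running
    return best


def random_ranked(rng, n):
    metric = np.sort(rng.normal(size=n))[::-1]
    genes = np.array([f"g{i:04d}" for i in range(n)], dtype=object)
    return RankedList(genes=genes, metric=metric)


class TestEnrichmentScore:
    def test_top_gene_unweighted_scores_one(self):
        ranked = random_ranked(np.random.default_rng(0), 10)
        es, _, leading = enrichment_score(ranked, {ranked.genes[0]}, exponent=0)
        assert es == pytest.approx(1.0)
        assert leading == (ranked.genes[0],)

    def test_bottom_set_scores_negative_with_full_leading_edge(self):
        genes = np.array([f"g{i}" for i in range(10)], dtype=object)
        ranked = RankedList(genes=genes, metric=np.ones(10))
        bottom = set(genes[-3:])
        es, _, leading = enrichment_score(ranked, bottom, exponent=1)
        assert es == pytest.approx(-1.0)
        assert set(leading) == bottom

    @pytest.mark.parametrize("exponent", [0.0, 1.0])
    def test_matches_naive_oracle_on_random_instances(self, exponent):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(20, 200))
            ranked = random_ranked(rng, n)
            k = int(rng.integers(1, max(2, n // 4)))
            gene_set = set(rng.choice(ranked.genes, size=k, replace=False))
            es, _, _ = enrichment_score(ranked, gene_set, exponent)
            expect = naive_es(ranked.genes, ranked.metric, gene_set, exponent)
            assert es == pytest.approx(expect, abs=1e-12)

    def test_disjoint_set_rejected(self):
        ranked = random_ranked(np.random.default_rng(1), 10)
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked, {"absent"})

    def test_reversed_list_negates_es_unweighted(self):
        rng = np.random.default_rng(22)
        n = 40
        metric = np.sort(rng.normal(size=n))[::-1]
        genes = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        ranked = RankedList(genes=genes, metric=metric)
        rev = RankedList(genes=genes[::-1].copy(), metric=(-metric[::-1]).copy())
        gene_set = set(rng.choice(genes, size=8, replace=False))
        es_f, _, _ = enrichment_score(ranked, gene_set, exponent=0)
        es_r, _, _ = enrichment_score(rev, gene_set, exponent=0)
        assert es_f == pytest.approx(-es_r, abs=1e-12)


class TestGseaSignificance:
    def test_exhaustive_p_matches_enumeration(self):
        ranked = random_ranked(np.random.default_rng(30), 8)
        gene_set = set(np.random.default_rng(31).choice(ranked.genes, 3, replace=False))
        res = gsea_significance(ranked, {"S": gene_set}, exhaustive=True, seed=0)
        # oracle: enumerate all C(8,3) sets with the naive scorer
        null = np.array(
            [
                naive_es(ranked.genes, ranked.metric, set(c), 1.0)
                for c in itertools.combinations(ranked.genes, 3)
            ]
        )
        es = naive_es(ranked.genes, ranked.metric, gene_set, 1.0)
        same = null[null >= 0] if es >= 0 else null[null < 0]
        expect = np.mean(np.abs(same) >= abs(es) - 1e-12)
        assert res.loc["S", "p_value"] == pytest.approx(expect, abs=1e-12)
        assert res.loc["S", "n_permutations"] == 56

    def test_planted_bottom_set_called_negative(self):
        rng = np.random.default_rng(32)
        ranked = random_ranked(rng, 1000)
        planted = set(ranked.genes[-30:])
        decoys = {
            f"D{i}": set(rng.choice(ranked.genes, 30, replace=False))
            for i in range(10)
        }
        res = gsea_significance(ranked, {"planted": planted, **decoys},
                                n_perm=500, seed=3)
        assert res.loc["planted", "nes"] < 0
        assert res.loc["planted", "fdr"] < 0.01

    def test_seed_determinism_and_perm_stability(self):
        rng = np.random.default_rng(33)
        ranked = random_ranked(rng, 300)
        sets = {f"S{i}": set(rng.choice(ranked.genes, 20, replace=False))
                for i in range(5)}
        a = gsea_significance(ranked, sets, n_perm=400, seed=9)
        b = gsea_significance(ranked, sets, n_perm=400, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = gsea_significance(ranked, sets, n_perm=800, seed=10)
        # doubling permutations moves p by no more than Monte-Carlo error
        for name in sets:
            p, n = a.loc[name, "p_value"], 400
            half_width = 4 * np.sqrt(max(p * (1 - p), 1e-4) / n)
            assert abs(c.loc[name, "p_value"] - p) <= half_width + 0.05


class TestSsgsea:
    def test_top_set_is_maximal_over_same_size_sets(self):
        rng = np.random.default_rng(40)
        expr = pd.Series(rng.normal(size=12),
                         index=[f"g{i}" for i in range(12)])
        order = expr.sort_values(ascending=False).index
        top = set(order[:3])
        top_score = ssgsea_score(expr, top)
        for combo in itertools.combinations(expr.index, 3):
            assert ssgsea_score(expr, set(combo)) <= top_score + 1e-12

    def test_monotone_in_in_set_expression(self):
        rng = np.random.default_rng(41)
        expr = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        gene_set = set(expr.sample(8, random_state=1).index)
        boosted = expr.copy()
        boosted.loc[sorted(gene_set)] += 5.0
        assert ssgsea_score(boosted, gene_set) > ssgsea_score(expr, gene_set)

    def test_rank_invariance(self):
        rng = np.random.default_rng(42)
        expr = pd.Series(rng.uniform(1, 10, size=30),
                         index=[f"g{i}" for i in range(30)])
        gene_set = set(expr.index[:5])
        assert ssgsea_score(expr, gene_set) == pytest.approx(
            ssgsea_score(np.log(expr), gene_set)
        )

    def test_disjoint_set_rejected(self):
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            ssgsea_score(expr, {"zzz"})


class TestHypergeomOra:
    def test_matches_direct_sum(self):
        universe = {f"g{i}" for i in range(100)}
        pathway = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        p, ratio, overlap = hypergeom_ora(query, pathway, universe)
        from math import comb
        expect = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(5, 11)
        ) / comb(100, 10)
        assert p == pytest.approx(expect, rel=1e-12)
        assert len(overlap) == 5
        assert ratio == pytest.approx((5 / 10) / (10 / 100))

    def test_zero_overlap_near_one(self):
        universe = {f"g{i}" for i in range(50)}
        p, _, overlap = hypergeom_ora(
            {"g0", "g1"}, {"g40", "g41"}, universe
        )
        assert not overlap and p > 0.9

    def test_query_equal_pathway_is_extremal(self):
        rng = np.random.default_rng(50)
        universe = {f"g{i}" for i in range(40)}
        pathway = set(rng.choice(sorted(universe), 6, replace=False))
        p_best, _, _ = hypergeom_ora(pathway, pathway, universe)
        for _ in range(20):
            q = set(rng.choice(sorted(universe), 6, replace=False))
            assert hypergeom_ora(q, pathway, universe)[0] >= p_best - 1e-15
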