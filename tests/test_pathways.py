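import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandcoop.datatypes import make_pair
from strandcoop.pathways import (
    activation_comparison,
    coordination_score,
    correlation_null_filter,
    cotarget_fraction,
    group_fold_changes,
    pathway_activation_scores,
    random_pair_rhos,
    recurrence_frequency,
    strand_pathway_ora,
    stratify_low_high_mixed,
)


class TestCoordinationScore:
    def test_identical_strand_footprints_give_zero(self):
        p = {f"g{i}" for i in range(20)}
        t = {f"g{i}" for i in range(5)}
        assert coordination_score(p, t, t) == 0.0

    def test_eight_vs_two_of_twenty(self):
        p = {f"g{i}" for i in range(20)}
        t5 = {f"g{i}" for i in range(8)}
        t3 = {f"g{i}" for i in range(8, 10)}
        assert coordination_score(p, t5, t3) == pytest.approx(0.3)

    def test_single_strand_twelve_of_twenty_fails_filter(self):
        p = {f"g{i}" for i in range(20)}
        t5 = {f"g{i}" for i in range(12)}
        score = coordination_score(p, t5, set())
        assert score == pytest.approx(0.6)
        assert not score < 0.5

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 15), st.integers(0, 15))
    def test_bounds_and_strand_symmetry(self, a, b):
        p = {f"g{i}" for i in range(15)}
        t5 = {f"g{i}" for i in range(a)}
        t3 = {f"g{i}" for i in range(15 - b, 15)}
        s = coordination_score(p, t5, t3)
        assert 0.0 <= s <= 1.0
        assert s == coordination_score(p, t3, t5)


class TestCotargetFraction:
    def test_disjoint_and_identical_extremes(self):
        pool = {"P": {f"g{i}" for i in range(10)}}
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(5, 10)}
        assert cotarget_fraction(a, b, pool)[1] == 0.0
        assert cotarget_fraction(a, a, pool)[1] == 1.0

    def test_set_arithmetic_example(self):
        pool = {"P": {"a", "b", "c", "d", "x"}}
        per, avg = cotarget_fraction({"a", "b", "c"}, {"c", "d"}, pool)
        assert per["P"] == pytest.approx(0.25)  # {c} over {a,b,c,d}
        assert avg == pytest.approx(0.25)

    def test_pathway_without_targets_skipped(self):
        pool = {"P": {"z1", "z2"}}
        per, avg = cotarget_fraction({"a"}, {"b"}, pool)
        assert per == {} and np.isnan(avg)


class TestRecurrence:
    @pytest.mark.parametrize(
        "hits,denom,expected,kept",
        [(4, 6, 4 / 6, True), (2, 6, 1 / 3, False), (6, 6, 1.0, True)],
    )
    def test_frequency_and_cutoff(self, hits, denom, expected, kept):
        f = recurrence_frequency(hits, denom)
        assert f == pytest.approx(expected)
        assert (f >= 0.5) is kept

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            recurrence_frequency(1, 0)


class TestCorrelationNullFilter:
    def test_separated_distributions_pass(self):
        rng = np.random.default_rng(60)
        edges = rng.normal(-0.7, 0.05, 30)
        random = rng.normal(0.0, 0.2, 5000)
        assert correlation_null_filter(edges, random) < 1e-10

    def test_identical_distributions_centered(self):
        rng = np.random.default_rng(61)
        random = rng.normal(0, 0.2, 5000)
        ps = [
            correlation_null_filter(rng.choice(random, 20, replace=False), random)
            for _ in range(200)
        ]
        assert 0.3 < np.median(ps) < 0.7
        assert np.mean(np.array(ps) < 0.05) <= 0.1

    def test_too_few_edges_fails_closed(self):
        assert correlation_null_filter([-0.9, -0.8], np.zeros(100)) == 1.0


class TestStratification:
    def test_perfectly_correlated_strands_leave_no_mixed(self):
        x = pd.Series(np.arange(20, dtype=float),
                      index=[f"s{i}" for i in range(20)])
        labels = stratify_low_high_mixed(x, 2 * x + 1)
        assert set(labels.unique()) == {"low", "high"}
        assert (labels == "low").sum() == 10

    def test_independent_strands_near_half_mixed(self):
        rng = np.random.default_rng(62)
        idx = [f"s{i}" for i in range(2000)]
        a = pd.Series(rng.normal(size=2000), index=idx)
        b = pd.Series(rng.normal(size=2000), index=idx)
        frac_mixed = (stratify_low_high_mixed(a, b) == "mixed").mean()
        assert 0.42 <= frac_mixed <= 0.58

    def test_all_tied_warns_all_mixed(self):
        idx = ["s1", "s2", "s3"]
        a = pd.Series([1.0, 1.0, 1.0], index=idx)
        with pytest.warns(UserWarning):
            labels = stratify_low_high_mixed(a, a)
        assert (labels == "mixed").all()

    def test_planted_targets_monotone_across_groups(self, tiny_cohort):
        truth = tiny_cohort.truth
        pair = truth.down_pairs[0]
        cancer = pair.affected_cancers[0]
        mi = tiny_cohort.mirna[cancer]
        labels = stratify_low_high_mixed(
            mi.normalized.loc[f"{pair.precursor_id}-5p", mi.tumor_samples],
            mi.normalized.loc[f"{pair.precursor_id}-3p", mi.tumor_samples],
        )
        genes = sorted(truth.planted_targets[f"{pair.precursor_id}-5p"])
        folds = group_fold_changes(tiny_cohort.mrna[cancer], genes, labels)
        med = folds.median()
        assert med["low"] > med["mixed"] > med["high"]


class TestOraAndActivation:
    def test_planted_pathway_top_ranked(self, tiny_cohort):
        from strandcoop.diffexpr import differential_expression
        from strandcoop.network import dysregulated_inverse_edges

        cancer = "C1"
        mirna_de = differential_expression(tiny_cohort.mirna[cancer])
        mrna_de = differential_expression(tiny_cohort.mrna[cancer])
        annotated, _ = dysregulated_inverse_edges(
            tiny_cohort.network, mirna_de, mrna_de,
            tiny_cohort.mirna[cancer], tiny_cohort.mrna[cancer],
        )
        pair = make_pair(tiny_cohort.truth.down_pairs[0].precursor_id)
        universe = set(tiny_cohort.mrna[cancer].features) & set().union(
            *tiny_cohort.pathways.values()
        )
        ora = strand_pathway_ora(
            annotated, pair, tiny_cohort.pathways, universe
        )
        both = ora[ora["query"] == "both"].sort_values("adj_p")
        assert both.iloc[0]["pathway"] == tiny_cohort.truth.planted_pathway
        assert both.iloc[0]["enriched"]
        # combined query dominates the 5p-only overlap per pathway
        merged = ora.pivot_table(index="pathway", columns="query", values="overlap")
        assert (merged["both"] >= merged["5p"].fillna(0)).all()

    def test_planted_suppression_detected_in_activation(self):
        # strands suppress the pathway: pathway-gene expression moves
        # opposite to strand expression across 48 samples
        rng = np.random.default_rng(63)
        samples = [f"s{i}" for i in range(48)]
        strand_level = rng.normal(size=48)
        genes = [f"g{i}" for i in range(200)]
        pathway = set(genes[:25])
        expr = pd.DataFrame(
            rng.normal(size=(200, 48)), index=genes, columns=samples
        )
        expr.loc[sorted(pathway)] -= 1.5 * strand_level
        from strandcoop.enrichment import ssgsea_score

        act = pd.Series(
            {s: ssgsea_score(expr[s], pathway) for s in samples}
        )
        strands = pd.DataFrame(
            {
                s: [strand_level[i] + rng.normal(0, 0.3),
                    strand_level[i] + rng.normal(0, 0.3)]
                for i, s in enumerate(samples)
            },
            index=["m-5p", "m-3p"],
        )
        out = activation_comparison(act, strands)
        assert len(out) == 2
        assert (out["p_value"] < 0.05).all()
        assert (out["median_high"] < out["median_low"]).all()

        # shuffled activation labels lose the signal most of the time
        shuffled = pd.Series(
            rng.permutation(act.to_numpy()), index=act.index
        )
        null = activation_comparison(shuffled, strands)
        assert (null["p_value"] > 0.01).all()

    def test_constant_activation_skipped(self):
        act = pd.Series(1.0, index=[f"s{i}" for i in range(20)])
        expr = pd.DataFrame(
            np.random.default_rng(0).normal(size=(2, 20)),
            index=["a-5p", "a-3p"], columns=act.index,
        )
        with pytest.warns(UserWarning):
            out = activation_comparison(act, expr)
        assert out.empty


def test_random_pair_rhos_centered(tiny_cohort):
    rhos = random_pair_rhos(
        tiny_cohort.mirna["C3"], tiny_cohort.mrna["C3"], n_random=2000, seed=1
    )
    assert abs(np.median(rhos)) < 0.1
    assert len(rhos) > 1900
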