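"""Pair-pathway coordination analysis.

For every pan-cancer dysregulated 5p/3p pair this module finds pathways
enriched among the pair's cancer-specific targets (hypergeometric ORA,
BH p < 0.05), then applies three high-confidence filters:

1. the pair's target-gene correlations must be significantly more
   negative than 10,000 random miRNA-gene pairs (one-sided Wilcoxon
   rank-sum, BH-adjusted p < 1e-3);
2. the coordination score |prop_5p - prop_3p| (absolute difference of
   the pathway fractions targeted by each strand) must be < 0.5 -- low
   values mean both strands carry comparable shares of the pathway;
3. the association must recur in at least 50% of the cancer types where
   the pair is concordantly dysregulated.

The co-targeting fraction (share of the pair's pathway-restricted
targets hit by both strands), low/high/mixed sample stratification, and
the pathway-activation (ssGSEA) comparison complete the picture.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .datatypes import ExpressionStudy, StrandPair, TargetNetwork
from .diffexpr import bh_adjust, spearman_pairs
from .enrichment import hypergeom_ora, ssgsea_score
from .network import strand_target_sets

__all__ = [
    "strand_pathway_ora",
    "random_pair_rhos",
    "correlation_null_filter",
    "coordination_score",
    "cotarget_fraction",
    "recurrence_frequency",
    "stratify_low_high_mixed",
    "group_fold_changes",
    "activation_comparison",
]


def strand_pathway_ora(
    annotated: TargetNetwork,
    pair: StrandPair,
    pathways: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ORA of the pair's 5p / 3p / combined target genes against pathways.

    The universe should be the measured genes of the cancer that are
    annotated to at least one pathway.  Returns one row per (query,
    pathway) with raw and BH-adjusted p (family = all pathways for one
    query); only pathways overlapping the universe are tested.
    """
    t5, t3, _ = strand_target_sets(annotated, pair)
    queries = {
        "5p": t5 & universe,
        "3p": t3 & universe,
        "both": (t5 | t3) & universe,
    }
    rows = []
    usable = {n: g for n, g in pathways.items() if g & universe}
    for label, query in queries.items():
        if not query:
            continue
        names, ps, ratios, overlaps = [], [], [], []
        for name in sorted(usable):
            p, ratio, overlap = hypergeom_ora(query, usable[name], universe)
            names.append(name)
            ps.append(p)
            ratios.append(ratio)
            overlaps.append(len(overlap))
        adj = bh_adjust(ps)
        for name, p, ratio, k, ap in zip(names, ps, ratios, overlaps, adj):
            rows.append(
                {
                    "query": label,
                    "pathway": name,
                    "p_value": p,
                    "adj_p": ap,
                    "ratio": ratio,
                    "overlap": k,
                    "enriched": bool(ap < alpha),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["query", "pathway", "p_value", "adj_p", "ratio", "overlap", "enriched"],
    )


def random_pair_rhos(
    mirna_study: ExpressionStudy,
    mrna_study: ExpressionStudy,
    n_random: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Spearman correlations of random (miRNA, gene) pairs in one cancer.

    Pairs are drawn uniformly from measured miRNA x measured genes (they
    may or may not be predicted targets); drawn once per cancer and
    reused for every pair-pathway filter test.
    """
    rng = np.random.default_rng(seed)
    common = [s for s in mirna_study.samples if s in set(mrna_study.samples)]
    mi = rng.integers(0, len(mirna_study.features), size=n_random)
    gi = rng.integers(0, len(mrna_study.features), size=n_random)
    x = mirna_study.normalized.loc[:, common].to_numpy()[mi]
    y = mrna_study.normalized.loc[:, common].to_numpy()[gi]
    rho, _ = spearman_pairs(x, y)
    return rho[np.isfinite(rho)]


def correlation_null_filter(edge_rhos, random_rhos) -> float:
    """One-sided Wilcoxon rank-sum p that edge correlations are more
    negative than the random-pair background.

    Fewer than 3 edges fails closed (p = 1): the pair-pathway link
    cannot be called high-confidence on that little evidence.  BH
    adjustment over all pair-pathway-cancer tests is the caller's job.
    """
    a = np.asarray(edge_rhos, dtype=float)
    a = a[np.isfinite(a)]
    b = np.asarray(random_rhos, dtype=float)
    if a.size < 3:
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="less", method="asymptotic")
    return float(res.pvalue)


def coordination_score(pathway_genes, targets_5p, targets_3p) -> float:
    """| |T5 ∩ P|/|P| - |T3 ∩ P|/|P| |, lower = more coordinated."""
    p = set(pathway_genes)
    if not p:
        raise ValueError("pathway gene set is empty")
    prop5 = len(set(targets_5p) & p) / len(p)
    prop3 = len(set(targets_3p) & p) / len(p)
    return abs(prop5 - prop3)


def cotarget_fraction(
    targets_5p, targets_3p, pathway_pool: dict[str, set[str]]
) -> tuple[dict[str, float], float]:
    """Per-pathway and average co-targeting fraction over a pathway pool.

    For each pathway P the fraction is |T5 ∩ T3 ∩ P| / |(T5 ∪ T3) ∩ P|
    (the Jaccard of the strand target sets restricted to P); pathways
    where the pair targets nothing are skipped.
    """
    t5, t3 = set(targets_5p), set(targets_3p)
    per_pathway = {}
    for name, genes in pathway_pool.items():
        union = (t5 | t3) & set(genes)
        if not union:
            continue
        per_pathway[name] = len(t5 & t3 & set(genes)) / len(union)
    avg = float(np.mean(list(per_pathway.values()))) if per_pathway else float("nan")
    return per_pathway, avg


def recurrence_frequency(n_hit_cancers: int, n_concordant_cancers: int) -> float:
    """Hits across cancers / concordantly dysregulated cancers of the pair."""
    if n_concordant_cancers < 1:
        raise ValueError("pair has no concordantly dysregulated cancers")
    if n_hit_cancers > n_concordant_cancers:
        raise ValueError("more hits than concordant cancers")
    return n_hit_cancers / n_concordant_cancers


def stratify_low_high_mixed(
    expr_5p: pd.Series, expr_3p: pd.Series
) -> pd.Series:
    """Label tumor samples low / high / mixed from the two strand levels.

    Each strand is median-split over the given samples; samples where
    both strands sit below their medians are ``low``, both at or above
    are ``high``, the remainder ``mixed``.  All-tied expression yields
    all-``mixed`` with a warning.
    """
    samples = expr_5p.index
    if not samples.equals(expr_3p.index):
        raise ValueError("strand expression vectors disagree on samples")
    if expr_5p.nunique() <= 1 and expr_3p.nunique() <= 1:
        warnings.warn("all-tied strand expression; every sample labeled mixed")
        return pd.Series("mixed", index=samples)
    lo5 = expr_5p < expr_5p.median()
    lo3 = expr_3p < expr_3p.median()
    labels = pd.Series("mixed", index=samples, dtype=object)
    labels[lo5 & lo3] = "low"
    labels[~lo5 & ~lo3] = "high"
    return labels


def group_fold_changes(
    mrna_study: ExpressionStudy, genes, labels: pd.Series, pseudo: float = 0.5
) -> pd.DataFrame:
    """Median per-gene log2 fold change (vs mean normal) in each group."""
    genes = [g for g in genes if g in mrna_study.features]
    normal_mean = mrna_study.normalized.loc[genes, mrna_study.normal_samples].mean(axis=1)
    out = {}
    for group in ("low", "mixed", "high"):
        samples = labels.index[labels == group]
        if len(samples) == 0:
            out[group] = pd.Series(np.nan, index=genes)
            continue
        expr = mrna_study.normalized.loc[genes, samples]
        lfc = np.log2((expr.add(pseudo, axis=0)).div(normal_mean + pseudo, axis=0))
        out[group] = lfc.median(axis=1)
    return pd.DataFrame(out)


def activation_comparison(
    activation: pd.Series,
    strand_expression: pd.DataFrame,
    quantile: float = 0.25,
    min_group: int = 5,
) -> pd.DataFrame:
    """Test whether strand expression is lower in high-activation samples.

    ``activation`` holds per-sample pathway activation (ssGSEA) scores;
    ``strand_expression`` is strands x samples.  Samples are split into
    the top and bottom activation quantile; per strand, a one-sided
    Wilcoxon rank-sum tests expression(high) < expression(low).  Returns
    an empty frame (with a warning) for constant scores or undersized
    groups; BH across strands x cancers is the caller's job.
    """
    act = activation.dropna()
    if act.nunique() <= 1:
        warnings.warn("constant activation scores; comparison skipped")
        return pd.DataFrame(columns=["strand", "p_value", "median_high", "median_low"])
    lo_cut = act.quantile(quantile)
    hi_cut = act.quantile(1 - quantile)
    low = act.index[act <= lo_cut]
    high = act.index[act >= hi_cut]
    if len(low) < min_group or len(high) < min_group:
        warnings.warn("activation quartile groups too small; comparison skipped")
        return pd.DataFrame(columns=["strand", "p_value", "median_high", "median_low"])
    rows = []
    for strand in strand_expression.index:
        e = strand_expression.loc[strand]
        res = stats.mannwhitneyu(
            e.loc[high], e.loc[low], alternative="less", method="asymptotic"
        )
        rows.append(
            {
                "strand": strand,
                "p_value": float(res.pvalue),
                "median_high": float(e.loc[high].median()),
                "median_low": float(e.loc[low].median()),
            }
        )
    return pd.DataFrame(rows)


def pathway_activation_scores(
    mrna_study: ExpressionStudy, pathway_genes, alpha: float = 0.25
) -> pd.Series:
    """ssGSEA activation score of one pathway in every tumor sample."""
    scores = {}
    for s in mrna_study.tumor_samples:
        scores[s] = ssgsea_score(mrna_study.normalized[s], pathway_genes, alpha=alpha)
    return pd.Series(scores, name="activation")
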