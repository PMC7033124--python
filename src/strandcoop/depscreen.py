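"""Survival/growth-modulating miRNA from dependency screens.

Per cell line, genes are ranked by their knockdown viability/growth
score (descending, so the genes the line depends on sit at the bottom).
Each mature miRNA's cancer-specific target set is evaluated by GSEA
against that ranking: a significantly negative NES (FDR < 0.1) means the
targets cluster among the essential genes, i.e. the miRNA potentially
restrains the line's survival/growth.  Calls are aggregated to
per-cancer association fractions, strand co-association, tumor-vs-screen
direction-consistency checks, and the final survival/growth pair
selection with the strand-balance rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import DependencyMatrix, StrandPair, TargetNetwork
from .enrichment import RankedList, gsea_significance

__all__ = [
    "rank_dependency",
    "screen_mirna",
    "association_summary",
    "strand_coassociation",
    "direction_consistency",
    "select_survival_growth_pairs",
]


def rank_dependency(dep: DependencyMatrix, cell_line: str) -> RankedList:
    """Ranked gene list of one cell line (dependency genes at the bottom)."""
    if cell_line not in dep.scores.columns:
        raise KeyError(f"unknown cell line {cell_line!r}")
    scores = dep.scores[cell_line].dropna()
    if len(scores) < 100:
        import warnings

        warnings.warn(f"cell line {cell_line!r} has <100 scored genes")
    return RankedList.from_scores(scores)


def screen_mirna(
    dep: DependencyMatrix,
    annotated_network: TargetNetwork,
    cancer_type: str,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA of every qualifying miRNA target set in every matched cell line.

    ``annotated_network`` must be the cancer-specific filtered network of
    ``cancer_type``; only its cell lines of matching lineage are screened.
    Target sets outside [min_set_size, max_set_size] are skipped.  Returns
    one row per (mature_id, cell_line) with NES, FDR and the associated
    flag (negative NES with FDR below the configured cutoff).
    """
    config = config or PipelineConfig()
    lines = dep.cell_lines_of(cancer_type)
    records = []
    if not lines:
        return pd.DataFrame(
            columns=[
                "mature_id", "cell_line", "platform", "cancer", "nes", "fdr",
                "es", "p_value", "associated", "leading_edge",
            ]
        )
    sets = {}
    for mature_id in sorted(annotated_network.mature_ids):
        targets = annotated_network.targets_of(mature_id)
        if config.min_set_size <= len(targets) <= config.max_set_size:
            sets[mature_id] = targets
    for j, line in enumerate(lines):
        ranked = rank_dependency(dep, line)
        present = {
            m: s for m, s in sets.items()
            if config.min_set_size <= len(ranked.positions_of(s))
        }
        if not present:
            continue
        res = gsea_significance(
            ranked,
            present,
            n_perm=config.gsea_permutations,
            seed=seed + j,
            exponent=config.gsea_exponent,
        )
        for mature_id, row in res.iterrows():
            records.append(
                {
                    "mature_id": mature_id,
                    "cell_line": line,
                    "platform": dep.platform,
                    "cancer": cancer_type,
                    "es": row["es"],
                    "nes": row["nes"],
                    "p_value": row["p_value"],
                    "fdr": row["fdr"],
                    "associated": bool(row["nes"] < 0 and row["fdr"] < config.nes_fdr),
                    "leading_edge": row["leading_edge"],
                }
            )
    return pd.DataFrame(records)


def association_summary(associations: pd.DataFrame) -> pd.DataFrame:
    """Per-(mature_id, cancer, platform) fraction of cell lines associated.

    The denominator is all screened cell lines of that cancer type.
    """
    if associations.empty:
        return pd.DataFrame(
            columns=["mature_id", "cancer", "platform", "n_lines", "n_associated", "fraction"]
        )
    grp = associations.groupby(["mature_id", "cancer", "platform"], sort=True)
    out = grp["associated"].agg(["size", "sum"]).reset_index()
    out = out.rename(columns={"size": "n_lines", "sum": "n_associated"})
    out["fraction"] = out["n_associated"] / out["n_lines"]
    return out


def strand_coassociation(
    associations: pd.DataFrame, pair: StrandPair
) -> dict:
    """Fraction of cell lines where both strands associate, among lines
    where at least one does.

    Also returns the per-FDR-cutoff empirical cumulative co-association
    curve used for the threshold-sensitivity display.
    """
    id5, id3 = pair.mature_ids
    sub = associations[associations["mature_id"].isin([id5, id3])]
    flags = sub.pivot_table(
        index="cell_line", columns="mature_id", values="associated",
        aggfunc="any", fill_value=False,
    )
    for mid in (id5, id3):
        if mid not in flags.columns:
            flags[mid] = False
    either = flags[id5] | flags[id3]
    both = flags[id5] & flags[id3]
    n_either = int(either.sum())
    fraction = float(both.sum() / n_either) if n_either else float("nan")

    curve = []
    fdr = sub.pivot_table(index="cell_line", columns="mature_id", values="fdr", aggfunc="min")
    neg = sub.pivot_table(index="cell_line", columns="mature_id", values="nes", aggfunc="min")
    for cutoff in np.arange(0.01, 0.26, 0.01):
        n_both = 0
        for line in fdr.index:
            ok = all(
                mid in fdr.columns
                and np.isfinite(fdr.loc[line, mid])
                and fdr.loc[line, mid] < cutoff
                and neg.loc[line, mid] < 0
                for mid in (id5, id3)
            )
            n_both += ok
        curve.append({"fdr_cutoff": round(float(cutoff), 2), "n_lines_both": n_both})
    return {
        "pair": pair.precursor_id,
        "n_lines_either": n_either,
        "n_lines_both": int(both.sum()),
        "coassociation_fraction": fraction,
        "fdr_curve": curve,
    }


def direction_consistency(
    associations: pd.DataFrame,
    mirna_de_by_cancer: dict[str, pd.DataFrame],
    mrna_de_by_cancer: dict[str, pd.DataFrame],
) -> dict:
    """Check that screen-associated miRNA are downregulated in matching
    tumors and their leading-edge genes upregulated.

    Returns per-platform fractions: of the (miRNA, cancer) combinations
    with at least one associated cell line, how many have a significant
    "down" call in that cancer's tumors; and of the leading-edge genes of
    associated (miRNA, cell line) evaluations, how many are called "up".
    """
    out = {}
    assoc = associations[associations["associated"]]
    for platform, sub in assoc.groupby("platform"):
        mirna_hits = mirna_total = 0
        gene_hits = gene_total = 0
        for (mature_id, cancer), grp in sub.groupby(["mature_id", "cancer"]):
            de = mirna_de_by_cancer.get(cancer)
            if de is None or mature_id not in de.index:
                continue
            mirna_total += 1
            mirna_hits += de.loc[mature_id, "call"] == "down"
            gde = mrna_de_by_cancer.get(cancer)
            if gde is None:
                continue
            leading = set().union(*(set(le) for le in grp["leading_edge"]))
            for gene in leading:
                if gene in gde.index:
                    gene_total += 1
                    gene_hits += gde.loc[gene, "call"] == "up"
        out[platform] = {
            "mirna_down_fraction": mirna_hits / mirna_total if mirna_total else float("nan"),
            "n_mirna_cancer": mirna_total,
            "leading_edge_up_fraction": gene_hits / gene_total if gene_total else float("nan"),
            "n_leading_edge_genes": gene_total,
        }
    return out


def select_survival_growth_pairs(
    summaries: pd.DataFrame,
    pair_dysregulations,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Final pair selection: both strands screen-associated on both
    platforms, pan-cancer concordant downregulation, and the strand
    balance annotation.

    A strand counts as associated on a platform when it has at least one
    associated cell line.  The 5p/3p association-fraction ratio (mean
    fraction across cancers, larger over smaller) is annotated and pairs
    with ratio below ``balance_ratio`` are flagged ``balanced``.
    """
    config = config or PipelineConfig()
    rows = []
    for dys in pair_dysregulations:
        pair = dys.pair
        id5, id3 = pair.mature_ids
        if not dys.pan_cancer:
            continue
        directions = [dys.direction_in(c) for c in dys.concordant_cancers]
        n_down = sum(d == "down" for d in directions)
        n_up = sum(d == "up" for d in directions)
        if n_down < config.down_up_bias * n_up or n_down == 0:
            continue
        per_platform_ok = {}
        fractions = {}
        for platform, sub in summaries.groupby("platform"):
            f5 = sub.loc[sub["mature_id"] == id5, "fraction"]
            f3 = sub.loc[sub["mature_id"] == id3, "fraction"]
            per_platform_ok[platform] = bool((f5 > 0).any() and (f3 > 0).any())
            fractions[platform] = (float(f5.mean()), float(f3.mean()))
        if len(per_platform_ok) < 2 or not all(per_platform_ok.values()):
            continue
        mean5 = np.nanmean([f[0] for f in fractions.values()])
        mean3 = np.nanmean([f[1] for f in fractions.values()])
        lo, hi = sorted([mean5, mean3])
        ratio = hi / lo if lo > 0 else float("inf")
        rows.append(
            {
                "precursor_id": pair.precursor_id,
                "fraction_5p": mean5,
                "fraction_3p": mean3,
                "association_ratio": ratio,
                "balanced": bool(ratio < config.balance_ratio),
                "n_concordant_cancers": len(dys.concordant_cancers),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "precursor_id", "fraction_5p", "fraction_3p",
            "association_ratio", "balanced", "n_concordant_cancers",
        ],
    )
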