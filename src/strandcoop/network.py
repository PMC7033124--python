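"""miRNA -> gene target network construction and cancer-specific filtering.

The base network is the union of prediction/curation sources (provenance
kept per edge).  Cancer-specific dysregulated edges then require the
inverse-dysregulation rule: a significantly downregulated miRNA with a
significantly upregulated target gene or vice versa, plus a negative
Spearman correlation with BH-adjusted p < 0.05 over the cohort samples.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import ExpressionStudy, StrandPair, TargetNetwork
from .diffexpr import bh_adjust, spearman_pairs

__all__ = ["union_targets", "dysregulated_inverse_edges", "strand_target_sets"]


def union_targets(source_tables: dict[str, pd.DataFrame]) -> TargetNetwork:
    """Union of target tables keyed by source label.

    Each table needs ``mature_id`` and ``gene_id`` columns.  An edge is
    present iff it appears in at least one source; its ``sources`` field
    is the ``;``-joined sorted set of contributing labels.
    """
    frames = []
    for label in sorted(source_tables):
        t = source_tables[label][["mature_id", "gene_id"]].drop_duplicates().copy()
        t["source"] = label
        frames.append(t)
    if not frames:
        return TargetNetwork(edges=pd.DataFrame(columns=list(TargetNetwork.REQUIRED)))
    stacked = pd.concat(frames, ignore_index=True)
    edges = (
        stacked.groupby(["mature_id", "gene_id"], sort=True)["source"]
        .agg(lambda s: ";".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"source": "sources"})
    )
    return TargetNetwork(edges=edges)


def dysregulated_inverse_edges(
    network: TargetNetwork,
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    mirna_study: ExpressionStudy,
    mrna_study: ExpressionStudy,
    alpha: float = 0.05,
    tumor_only: bool = False,
) -> tuple[TargetNetwork, dict]:
    """Cancer-specific miRNA-mediated suppression edges.

    An edge survives iff the DE calls are opposite in sign
    ((down, up) or (up, down)) and the miRNA-gene Spearman correlation
    is negative with BH-adjusted p < ``alpha`` (the BH family being all
    DE-consistent candidate edges of this cancer).  Correlations use all
    samples (tumor + normal pooled) unless ``tumor_only`` is set.

    Returns the annotated network plus a report dict counting dropped
    edges by reason.
    """
    edges = network.edges.copy()
    report = {"input_edges": int(len(edges))}

    mirna_calls = mirna_de["call"]
    mrna_calls = mrna_de["call"]
    edges["call_mirna"] = edges["mature_id"].map(mirna_calls)
    edges["call_gene"] = edges["gene_id"].map(mrna_calls)
    unexpressed = edges["call_mirna"].isna() | edges["call_gene"].isna()
    report["dropped_unexpressed"] = int(unexpressed.sum())
    edges = edges[~unexpressed]

    inverse = (
        ((edges["call_mirna"] == "down") & (edges["call_gene"] == "up"))
        | ((edges["call_mirna"] == "up") & (edges["call_gene"] == "down"))
    )
    report["dropped_not_inverse_de"] = int((~inverse).sum())
    edges = edges[inverse].reset_index(drop=True)

    if edges.empty:
        report["retained"] = 0
        annotated = edges.assign(rho=[], adj_p=[], cancer=[])
        return TargetNetwork(edges=annotated), report

    samples = (
        mirna_study.tumor_samples if tumor_only else mirna_study.samples
    )
    common = [s for s in samples if s in set(mrna_study.samples)]
    x = mirna_study.normalized.loc[edges["mature_id"], common].to_numpy()
    y = mrna_study.normalized.loc[edges["gene_id"], common].to_numpy()
    rho, p = spearman_pairs(x, y)
    edges["rho"] = rho
    edges["adj_p"] = bh_adjust(pd.Series(p).fillna(1.0).to_numpy())
    keep = (edges["rho"] < 0) & (edges["adj_p"] < alpha)
    report["dropped_correlation"] = int((~keep).sum())
    edges = edges[keep].reset_index(drop=True)
    edges["cancer"] = mirna_study.cancer_type
    report["retained"] = int(len(edges))
    annotated = edges.drop(columns=["call_mirna", "call_gene"])
    return TargetNetwork(edges=annotated), report


def strand_target_sets(
    annotated: TargetNetwork, pair: StrandPair
) -> tuple[set[str], set[str], set[str]]:
    """(targets_5p, targets_3p, co_targets) of one pair in one cancer."""
    t5 = annotated.targets_of(pair.mature_5p.mature_id)
    t3 = annotated.targets_of(pair.mature_3p.mature_id)
    return t5, t3, t5 & t3
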