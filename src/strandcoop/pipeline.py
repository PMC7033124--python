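"""End-to-end orchestration of the strand-cooperativity pipeline.

Stages (each writes a JSON report and TSV tables when ``out_dir`` is
given, every report embedding the config hash and seed):

1. simulate    -- synthetic multi-cancer cohort with planted truth
2. diffexpr    -- per-cancer miRNA/mRNA differential expression
3. concordance -- strand pairing, fold-change concordance, pan-cancer pairs
4. network     -- cancer-specific inverse dysregulated target edges
5. depscreen   -- dependency-screen GSEA, co-association, pair selection
6. pathways    -- pair-pathway ORA + high-confidence filters + recurrence
7. regress     -- confounder-adjusted fits + rank-product recurrence
8. survive     -- four-strand signature survival analysis

Running twice with the same seed and configuration reproduces identical
outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as conc
from . import depscreen as ds
from . import diffexpr as de
from . import network as net
from . import pathways as pw
from . import regression as reg
from . import survival as sv
from .config import PipelineConfig
from .datatypes import TargetNetwork
from .io import write_json_report, write_matrix_tsv
from .simulate import (
    Cohort,
    SimulationConfig,
    simulate_cohort,
    simulate_dependency,
    simulate_perturbation,
    simulate_survival,
)

logger = logging.getLogger("strandcoop")

__all__ = ["run_pipeline"]


def _maybe_write(df: pd.DataFrame, out_dir, name: str) -> None:
    if out_dir is not None:
        path = Path(out_dir) / name
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t")


def stage_diffexpr(cohort: Cohort, config: PipelineConfig):
    mirna_de, mrna_de = {}, {}
    for cancer in cohort.config.cancers:
        mirna_de[cancer] = de.differential_expression(cohort.mirna[cancer], config)
        mrna_de[cancer] = de.differential_expression(cohort.mrna[cancer], config)
        logger.info(
            "diffexpr %s: %d miRNA / %d mRNA tested",
            cancer, len(mirna_de[cancer]), len(mrna_de[cancer]),
        )
    return mirna_de, mrna_de


def stage_concordance(cohort: Cohort, mirna_de, config: PipelineConfig, seed: int):
    mature_ids = list(cohort.mirna[cohort.config.cancers[0]].features)
    pairs, singletons = conc.pair_strands(mature_ids)

    # within-pair expression correlation vs cross-precursor background
    pair_rhos, bg_rhos = [], []
    n_bg = config.background_multiplier * len(pairs)
    for i, cancer in enumerate(cohort.config.cancers):
        norm = cohort.mirna[cancer].normalized
        x5 = norm.loc[[p.mature_5p.mature_id for p in pairs]].to_numpy()
        x3 = norm.loc[[p.mature_3p.mature_id for p in pairs]].to_numpy()
        rho, _ = de.spearman_pairs(x5, x3)
        pair_rhos.extend(rho[np.isfinite(rho)])
        bg = conc.background_pairs(mature_ids, n_bg, seed=seed + i)
        b1 = norm.loc[[a for a, _ in bg]].to_numpy()
        b2 = norm.loc[[b for _, b in bg]].to_numpy()
        brho, _ = de.spearman_pairs(b1, b2)
        bg_rhos.extend(brho[np.isfinite(brho)])
    shift_p = conc.concordance_shift(pair_rhos, bg_rhos)

    dysregulations = [
        conc.build_pair_dysregulation(p, mirna_de, config.min_cancers) for p in pairs
    ]
    fold_rows = []
    for d in dysregulations:
        for cancer, row in d.per_cancer.iterrows():
            fold_rows.append(
                {
                    "precursor_id": d.pair.precursor_id,
                    "cancer": cancer,
                    "log2fc_5p": row["log2fc_5p"],
                    "log2fc_3p": row["log2fc_3p"],
                    "call_5p": row["call_5p"],
                    "call_3p": row["call_3p"],
                }
            )
    fold_table = pd.DataFrame(fold_rows)
    fold_rho = conc.foldchange_concordance(fold_table)
    selected, direction_table = conc.pan_cancer_pairs(dysregulations)
    return {
        "pairs": pairs,
        "singletons": singletons,
        "dysregulations": dysregulations,
        "selected": selected,
        "direction_table": direction_table,
        "fold_table": fold_table,
        "foldchange_rho": fold_rho,
        "shift_p": shift_p,
        "pair_rhos": np.asarray(pair_rhos),
        "background_rhos": np.asarray(bg_rhos),
    }


def stage_network(cohort: Cohort, mirna_de, mrna_de, config: PipelineConfig):
    annotated, reports = {}, {}
    for cancer in cohort.config.cancers:
        annotated[cancer], reports[cancer] = net.dysregulated_inverse_edges(
            cohort.network,
            mirna_de[cancer],
            mrna_de[cancer],
            cohort.mirna[cancer],
            cohort.mrna[cancer],
            alpha=config.alpha,
        )
        logger.info("network %s: %d edges retained", cancer, len(annotated[cancer]))
    return annotated, reports


def stage_depscreen(
    cohort: Cohort, annotated, concordance_result, mirna_de, mrna_de,
    config: PipelineConfig, seed: int,
):
    lineages = sorted(cohort.truth.affected_lineages() | set(cohort.config.cancers))
    genes = list(cohort.mrna[cohort.config.cancers[0]].features)
    platforms = {}
    for platform in ("rnai", "crispr"):
        platforms[platform] = simulate_dependency(
            cohort.truth, genes, lineages, platform,
            lines_per_lineage=cohort.config.lines_per_lineage,
            noise_sd=cohort.config.dependency_noise_sd,
            seed=seed,
        )
    assoc_frames = []
    for platform, dep in platforms.items():
        for i, cancer in enumerate(cohort.config.cancers):
            frame = ds.screen_mirna(
                dep, annotated[cancer], cancer, config, seed=seed + 1000 * i
            )
            if not frame.empty:
                assoc_frames.append(frame)
    associations = (
        pd.concat(assoc_frames, ignore_index=True)
        if assoc_frames
        else pd.DataFrame(
            columns=["mature_id", "cell_line", "platform", "cancer", "es",
                     "nes", "p_value", "fdr", "associated", "leading_edge"]
        )
    )
    summaries = ds.association_summary(associations)
    coassociation = {
        d.pair.precursor_id: ds.strand_coassociation(associations, d.pair)
        for d in concordance_result["selected"]
    }
    consistency = ds.direction_consistency(associations, mirna_de, mrna_de)
    selected_pairs = ds.select_survival_growth_pairs(
        summaries, concordance_result["dysregulations"], config
    )
    return {
        "dependency": platforms,
        "associations": associations,
        "summaries": summaries,
        "coassociation": coassociation,
        "direction_consistency": consistency,
        "selected_pairs": selected_pairs,
    }


def stage_pathways(
    cohort: Cohort, annotated, concordance_result, config: PipelineConfig, seed: int
):
    records = []
    random_rho_cache = {}
    pathway_gene_union = set().union(*cohort.pathways.values())
    for dys in concordance_result["selected"]:
        pair = dys.pair
        for cancer in sorted(dys.concordant_cancers):
            network_c = annotated[cancer]
            mrna = cohort.mrna[cancer]
            universe = set(mrna.features) & pathway_gene_union
            ora = pw.strand_pathway_ora(
                network_c, pair, cohort.pathways, universe, alpha=config.alpha
            )
            if ora.empty:
                continue
            t5, t3, _ = net.strand_target_sets(network_c, pair)
            if cancer not in random_rho_cache:
                random_rho_cache[cancer] = pw.random_pair_rhos(
                    cohort.mirna[cancer], mrna,
                    n_random=config.n_random_pairs, seed=seed + 17,
                )
            wide = ora.pivot_table(index="pathway", columns="query", values="adj_p")
            edges = network_c.edges
            pair_edges = edges[edges["mature_id"].isin(pair.mature_ids)]
            for pathway, row in wide.iterrows():
                enriched = bool(row.get("both", 1.0) < config.alpha)
                if not enriched:
                    continue
                genes_p = cohort.pathways[pathway] & set(mrna.features)
                edge_rhos = pair_edges.loc[
                    pair_edges["gene_id"].isin(genes_p), "rho"
                ].to_numpy()
                wilcoxon_p = pw.correlation_null_filter(
                    edge_rhos, random_rho_cache[cancer]
                )
                coord = pw.coordination_score(genes_p, t5, t3)
                records.append(
                    {
                        "precursor_id": pair.precursor_id,
                        "pathway": pathway,
                        "cancer": cancer,
                        "ora_adj_p_5p": float(row.get("5p", np.nan)),
                        "ora_adj_p_3p": float(row.get("3p", np.nan)),
                        "ora_adj_p_both": float(row.get("both", np.nan)),
                        "wilcoxon_p": wilcoxon_p,
                        "coordination": coord,
                        "n_edges": int(
                            pair_edges["gene_id"].isin(genes_p).sum()
                        ),
                    }
                )
    table = pd.DataFrame(records)
    if not table.empty:
        table["wilcoxon_adj_p"] = de.bh_adjust(table["wilcoxon_p"].to_numpy())
        table["high_confidence"] = (
            (table["wilcoxon_adj_p"] < config.wilcoxon_alpha)
            & (table["coordination"] < config.coordination_cutoff)
        )
    else:
        table = pd.DataFrame(
            columns=[
                "precursor_id", "pathway", "cancer", "ora_adj_p_5p",
                "ora_adj_p_3p", "ora_adj_p_both", "wilcoxon_p", "coordination",
                "n_edges", "wilcoxon_adj_p", "high_confidence",
            ]
        )

    concordant_counts = {
        d.pair.precursor_id: len(d.concordant_cancers)
        for d in concordance_result["selected"]
    }
    rec_rows = []
    hc = table[table["high_confidence"]]
    for (precursor, pathway), grp in hc.groupby(["precursor_id", "pathway"]):
        denom = concordant_counts.get(precursor, 0)
        if denom < 1:
            continue
        freq = pw.recurrence_frequency(grp["cancer"].nunique(), denom)
        rec_rows.append(
            {
                "precursor_id": precursor,
                "pathway": pathway,
                "n_hit_cancers": int(grp["cancer"].nunique()),
                "n_concordant_cancers": denom,
                "recurrence": freq,
                "mean_coordination": float(grp["coordination"].mean()),
                "recurrent": bool(freq >= config.recurrence_cutoff),
            }
        )
    recurrence = pd.DataFrame(
        rec_rows,
        columns=[
            "precursor_id", "pathway", "n_hit_cancers", "n_concordant_cancers",
            "recurrence", "mean_coordination", "recurrent",
        ],
    ).sort_values(
        ["recurrence", "mean_coordination"], ascending=[False, True]
    ) if rec_rows else pd.DataFrame(
        columns=[
            "precursor_id", "pathway", "n_hit_cancers", "n_concordant_cancers",
            "recurrence", "mean_coordination", "recurrent",
        ]
    )

    # co-targeting fraction over each pair's coordinated pathway pool
    cotarget = {}
    for dys in concordance_result["selected"]:
        pair = dys.pair
        pool_names = set(
            hc.loc[hc["precursor_id"] == pair.precursor_id, "pathway"]
        )
        if not pool_names:
            continue
        per_cancer_fracs = []
        for cancer in sorted(dys.concordant_cancers):
            t5, t3, _ = net.strand_target_sets(annotated[cancer], pair)
            _, avg = pw.cotarget_fraction(
                t5, t3, {n: cohort.pathways[n] for n in pool_names}
            )
            if np.isfinite(avg):
                per_cancer_fracs.append(avg)
        if per_cancer_fracs:
            cotarget[pair.precursor_id] = float(np.mean(per_cancer_fracs))

    return {"table": table, "recurrence": recurrence, "cotarget_fraction": cotarget}


def stage_regress(
    cohort: Cohort, annotated, config: PipelineConfig, seed: int
):
    fit_rows = []
    for cancer in cohort.config.cancers:
        edges = annotated[cancer].edges
        if edges.empty:
            continue
        mrna = cohort.mrna[cancer]
        mirna = cohort.mirna[cancer]
        cov = cohort.covariates[cancer]
        tumor = [s for s in mrna.tumor_samples if s in set(mirna.tumor_samples)]
        y_all = np.log2(mrna.normalized.loc[:, tumor] + 1.0)
        x_mir_all = np.log2(mirna.normalized.loc[:, tumor] + 1.0)

        def _std(v):
            sd = v.std()
            return (v - v.mean()) / (sd if sd > 0 else 1.0)

        ps = []
        for _, edge in edges.iterrows():
            g, m = edge["gene_id"], edge["mature_id"]
            if g not in cov.methylation.index or g not in y_all.index:
                continue
            fit = reg.fit_multivariate(
                y_all.loc[g].to_numpy(),
                _std(cov.methylation.loc[g, tumor]).to_numpy(),
                _std(cov.copy_number.loc[g, tumor]).to_numpy(),
                _std(x_mir_all.loc[m]).to_numpy(),
            )
            if fit.collinear:
                continue
            fit_rows.append(
                {
                    "gene": g, "mirna": m, "cancer": cancer,
                    "beta_mir": fit.beta_mir, "beta_dm": fit.beta_dm,
                    "beta_cnv": fit.beta_cnv, "se_mir": fit.se_mir,
                    "p_mir": fit.p_mir, "n": fit.n,
                }
            )
            ps.append(fit.p_mir)
    fits = pd.DataFrame(fit_rows)
    if not fits.empty:
        fits["adj_p_mir"] = np.nan
        for cancer, grp in fits.groupby("cancer"):
            fits.loc[grp.index, "adj_p_mir"] = de.bh_adjust(grp["p_mir"].to_numpy())
        matrix = reg.coefficient_matrix(fits)
    else:
        matrix = pd.DataFrame()
    if matrix.empty or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        recurrence = pd.DataFrame()
    else:
        recurrence = reg.rank_product(
            matrix, direction="inverse",
            n_perm=min(config.rank_product_permutations, 2000),
            seed=seed + 23,
        )

    # essential-gene depletion analogue: perturb one planted strand
    depletion = {}
    strands = cohort.truth.signature_strands
    if strands:
        mature_id = strands[0]
        pert = simulate_perturbation(cohort, mature_id, effect=1.0, seed=seed + 29)
        lfc = de.log2_fold_change(pert)
        essential = cohort.truth.dependency_genes()
        targets = set(cohort.truth.planted_targets[mature_id])
        target_essential = targets & essential
        background = set(pert.features) - target_essential
        depletion = reg.essential_depletion_test(lfc, target_essential, background)
        depletion["mature_id"] = mature_id
    return {"fits": fits, "matrix": matrix, "recurrence": recurrence,
            "essential_depletion": depletion}


def stage_survive(cohort: Cohort, config: PipelineConfig, seed: int):
    strands = cohort.truth.signature_strands
    per_cancer_scores = {}
    for cancer in cohort.config.cancers:
        study = cohort.mirna[cancer]
        per_cancer_scores[cancer] = sv.signature_score(
            study.normalized.loc[:, study.tumor_samples], strands
        )
    pooled = pd.concat(per_cancer_scores.values())
    clinical = simulate_survival(
        pooled, cohort.truth.survival_effect,
        censoring_rate=cohort.config.censoring_rate, seed=seed + 31,
        baseline_median_months=cohort.config.baseline_median_months,
    )
    clinical = sv.truncate_followup(clinical, config.horizon_months)
    quartiles = sv.quartile_stratify(clinical["signature"])
    clinical["quartile"] = quartiles

    q1 = clinical[clinical["quartile"] == "Q1"]
    q4 = clinical[clinical["quartile"] == "Q4"]
    km_q1, median_q1 = sv.kaplan_meier(q1["time_months"], q1["event"])
    km_q4, median_q4 = sv.kaplan_meier(q4["time_months"], q4["event"])
    chi2, logrank_p = sv.logrank_test(
        q1["time_months"], q1["event"], q4["time_months"], q4["event"]
    )

    sub = pd.concat([q1, q4])
    covs = pd.DataFrame(
        {
            "signature_q4": (sub["quartile"] == "Q4").astype(float),
            "age_high": (sub["age"] >= sub["age"].median()).astype(float),
            "grade": sub["grade"].astype(float),
            "stage_late": (sub["stage"] == "late").astype(float),
        },
        index=sub.index,
    )
    uni = sv.cox_fit(covs[["signature_q4"]], sub["time_months"], sub["event"])
    multi = sv.cox_fit(covs, sub["time_months"], sub["event"])

    # per-cancer signature-variant comparison
    variants = {f"{s}": [s] for s in strands}
    for pair in cohort.truth.down_pairs:
        variants[f"{pair.precursor_id}-both"] = [
            f"{pair.precursor_id}-5p", f"{pair.precursor_id}-3p"
        ]
    variants["four-strand"] = list(strands)
    variant_p: dict[str, dict[str, float]] = {name: {} for name in variants}
    for cancer in cohort.config.cancers:
        study = cohort.mirna[cancer]
        patients = [p for p in clinical.index if p in set(study.tumor_samples)]
        if len(patients) < 8:
            continue
        sub_c = clinical.loc[patients]
        for name, strand_list in variants.items():
            score = sv.signature_score(
                study.normalized.loc[:, patients], strand_list
            )
            labels = sv.quartile_stratify(score)
            a = sub_c[labels == "Q1"]
            b = sub_c[labels == "Q4"]
            if a["event"].sum() == 0 and b["event"].sum() == 0:
                continue
            _, p = sv.logrank_test(
                a["time_months"], a["event"], b["time_months"], b["event"]
            )
            variant_p[name][cancer] = p
    try:
        variant_comparison_p = sv.compare_signatures(variant_p, "four-strand")
    except (ValueError, KeyError):
        variant_comparison_p = float("nan")

    return {
        "clinical": clinical,
        "km_q1": km_q1, "km_q4": km_q4,
        "median_q1": median_q1, "median_q4": median_q4,
        "logrank_chi2": chi2, "logrank_p": logrank_p,
        "cox_univariate": uni, "cox_multivariate": multi,
        "variant_logrank_p": variant_p,
        "variant_comparison_p": variant_comparison_p,
    }


def run_pipeline(
    config: PipelineConfig | None = None,
    sim_config: SimulationConfig | None = None,
    seed: int = 0,
    out_dir=None,
    stages: set[str] | None = None,
) -> dict:
    """Run the full pipeline on a simulated cohort; return all results.

    ``stages`` restricts execution (prerequisite stages always run);
    ``out_dir`` enables JSON/TSV report writing.
    """
    config = config or PipelineConfig()
    sim_config = sim_config or SimulationConfig()
    chash = config.config_hash()
    results: dict = {"seed": seed, "config_hash": chash}
    want = stages or {
        "diffexpr", "concordance", "network", "depscreen",
        "pathways", "regress", "survive",
    }

    cohort = simulate_cohort(sim_config, seed=seed)
    results["cohort"] = cohort
    logger.info("simulated cohort: %d cancers, seed %d", sim_config.n_cancers, seed)

    mirna_de, mrna_de = stage_diffexpr(cohort, config)
    results["mirna_de"] = mirna_de
    results["mrna_de"] = mrna_de

    concordance_result = stage_concordance(cohort, mirna_de, config, seed)
    results["concordance"] = concordance_result

    annotated, net_reports = stage_network(cohort, mirna_de, mrna_de, config)
    results["network"] = annotated
    results["network_reports"] = net_reports

    if "depscreen" in want or "pathways" in want or "regress" in want:
        results["depscreen"] = stage_depscreen(
            cohort, annotated, concordance_result, mirna_de, mrna_de, config, seed
        )
    if "pathways" in want:
        results["pathways"] = stage_pathways(
            cohort, annotated, concordance_result, config, seed
        )
    if "regress" in want:
        results["regress"] = stage_regress(cohort, annotated, config, seed)
    if "survive" in want:
        results["survive"] = stage_survive(cohort, config, seed)

    if out_dir is not None:
        _write_reports(results, config, seed, Path(out_dir))
    return results


def _write_reports(results, config: PipelineConfig, seed: int, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    cohort: Cohort = results["cohort"]
    cohort.truth.to_json(out_dir / "ground_truth.json")

    for cancer, table in results["mirna_de"].items():
        _maybe_write(table, out_dir, f"diffexpr/{cancer}.mirna.tsv")
    for cancer, table in results["mrna_de"].items():
        _maybe_write(table, out_dir, f"diffexpr/{cancer}.mrna.tsv")

    cr = results["concordance"]
    _maybe_write(cr["fold_table"].set_index("precursor_id"), out_dir,
                 "concordance/fold_table.tsv")
    write_json_report(
        {
            "foldchange_rho": cr["foldchange_rho"].rho,
            "foldchange_rho_p": cr["foldchange_rho"].p_value,
            "shift_p": cr["shift_p"],
            "n_pairs": len(cr["pairs"]),
            "n_pan_cancer_pairs": len(cr["selected"]),
            "pan_cancer_pairs": [d.pair.precursor_id for d in cr["selected"]],
        },
        out_dir / "concordance/report.json",
        config_hash=chash, seed=seed,
    )
    for cancer, network in results["network"].items():
        _maybe_write(network.edges.set_index("mature_id"), out_dir,
                     f"network/{cancer}.edges.tsv")
    write_json_report(
        results["network_reports"], out_dir / "network/report.json",
        config_hash=chash, seed=seed,
    )
    if "depscreen" in results:
        dsr = results["depscreen"]
        assoc = dsr["associations"].copy()
        if not assoc.empty:
            assoc["leading_edge"] = assoc["leading_edge"].map(
                lambda le: ",".join(le)
            )
        _maybe_write(assoc.set_index("mature_id") if not assoc.empty else assoc,
                     out_dir, "depscreen/associations.tsv")
        _maybe_write(dsr["summaries"], out_dir, "depscreen/summaries.tsv")
        _maybe_write(dsr["selected_pairs"], out_dir, "depscreen/selected_pairs.tsv")
        write_json_report(
            {
                "coassociation": dsr["coassociation"],
                "direction_consistency": dsr["direction_consistency"],
                "selected_pairs": dsr["selected_pairs"]["precursor_id"].tolist()
                if not dsr["selected_pairs"].empty else [],
            },
            out_dir / "depscreen/report.json", config_hash=chash, seed=seed,
        )
    if "pathways" in results:
        pr = results["pathways"]
        _maybe_write(pr["table"], out_dir, "pathways/pair_pathway.tsv")
        _maybe_write(pr["recurrence"], out_dir, "pathways/recurrence.tsv")
        write_json_report(
            {"cotarget_fraction": pr["cotarget_fraction"]},
            out_dir / "pathways/report.json", config_hash=chash, seed=seed,
        )
    if "regress" in results:
        rr = results["regress"]
        _maybe_write(rr["fits"], out_dir, "regress/fits.tsv")
        _maybe_write(rr["recurrence"], out_dir, "regress/recurrence.tsv")
        write_json_report(
            {"essential_depletion": rr["essential_depletion"]},
            out_dir / "regress/report.json", config_hash=chash, seed=seed,
        )
    if "survive" in results:
        svr = results["survive"]
        _maybe_write(svr["clinical"], out_dir, "survive/clinical.tsv")
        write_json_report(
            {
                "logrank_chi2": svr["logrank_chi2"],
                "logrank_p": svr["logrank_p"],
                "median_q1": svr["median_q1"],
                "median_q4": svr["median_q4"],
                "cox_univariate": [vars(r) for r in svr["cox_univariate"]],
                "cox_multivariate": [vars(r) for r in svr["cox_multivariate"]],
                "variant_comparison_p": svr["variant_comparison_p"],
            },
            out_dir / "survive/report.json", config_hash=chash, seed=seed,
        )
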