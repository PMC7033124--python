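"""Synthetic multi-cancer cohorts with planted ground truth.

The generator emulates the statistical structure the downstream stages
assume, so every stage is testable without external downloads:

* miRNA counts are negative binomial (mean mu, dispersion phi with
  var = mu + phi mu^2, the count-model convention shared with the DE
  stage) with log-normal library sizes.  Both arms of a precursor share
  a per-sample latent abundance, which creates the within-pair
  expression correlation that random cross-precursor pairs lack, and a
  shared per-cancer fold component, which creates fold-change
  concordance.  Planted 5p/3p pairs carry a fixed concordant log2 fold
  change in a configurable majority of cancers.
* target mRNA means couple log-linearly to the standardized expression
  of their regulating miRNA with a negative coefficient (beta_miR), on
  top of methylation and copy-number confounder terms (beta_DM,
  beta_CNV), so inverse correlation, confounded regression, and
  perturbation responses all have a recoverable truth.
* dependency screens shift planted target genes down (more essential)
  in cell lines of the affected lineages; two platforms share the truth
  but carry independent noise.
* survival times are exponential with hazard lambda0 * HR^z where z is
  the standardized four-strand signature; censoring is independent.

All randomness flows from a single integer seed through spawned
``numpy`` generators, so identical seeds give identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CovariateMatrices,
    DependencyMatrix,
    ExpressionStudy,
    TargetNetwork,
    make_pair,
)

__all__ = [
    "SimulationConfig",
    "PlantedPair",
    "GroundTruth",
    "Cohort",
    "simulate_cohort",
    "simulate_dependency",
    "simulate_survival",
    "simulate_perturbation",
]

SOURCES = ("scan", "miner", "curated")


@dataclass
class SimulationConfig:
    """Shape and effect sizes of the default synthetic study.

    The default cohort: 8 cancers with 30 tumor + 15 normal samples
    each, 60 precursors contributing both arms plus 80 singleton mature
    miRNA (200 mature total), 2,000 genes, 20 pathways of 50 genes, and
    12 cell lines per lineage -- sized so a full pipeline run stays in
    the minutes range on one CPU.
    """

    n_cancers: int = 8
    n_tumor: int = 30
    n_normal: int = 15
    n_precursors: int = 60
    n_singletons: int = 80
    n_genes: int = 2000
    n_pathways: int = 20
    pathway_size: int = 50
    # count model
    nb_dispersion: float = 0.15
    library_log_sd: float = 0.3
    latent_log2_sd: float = 0.5
    arm_noise_log2_sd: float = 0.15
    shared_fold_log2_sd: float = 0.35
    background_de_sd: float = 0.3
    background_de_fraction: float = 0.1
    # planted effects
    n_planted_down: int = 2
    n_planted_up: int = 1
    pair_log2fc: float = 1.5
    affected_cancers: int = 6
    targets_per_strand: int = 40
    pathway_targets_per_strand: int = 20
    cotarget_overlap: int = 8
    beta_mir: float = -0.8
    decoy_targets: int = 15
    # confounders
    n_confounded_genes: int = 300
    beta_dm: float = -1.5
    beta_cnv: float = 0.5
    # dependency screens
    lines_per_lineage: int = 12
    dependency_effect: float = 1.0
    dependency_noise_sd: float = 0.3
    # survival
    survival_hr: float = 0.3
    censoring_rate: float = 0.3
    baseline_median_months: float = 60.0

    def __post_init__(self) -> None:
        if self.n_cancers < 1:
            raise ValueError("need at least one cancer type")
        if min(self.n_tumor, self.n_normal) < 3:
            raise ValueError("need >=3 samples per arm")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.affected_cancers > self.n_cancers:
            raise ValueError("affected_cancers exceeds n_cancers")

    @property
    def cancers(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_cancers)]


@dataclass
class PlantedPair:
    precursor_id: str
    direction: str  # "down" or "up" in tumors
    log2fc: float   # signed effect in affected cancers
    affected_cancers: list[str]


@dataclass
class GroundTruth:
    planted_pairs: list[PlantedPair]
    planted_targets: dict[str, dict[str, float]]  # mature -> gene -> beta_miR
    planted_pathway: str
    up_pathway: str
    dependency_effect: float
    survival_effect: float
    confounder_effects: dict[str, tuple[float, float]]  # gene -> (beta_DM, beta_CNV)

    @property
    def down_pairs(self) -> list[PlantedPair]:
        return [p for p in self.planted_pairs if p.direction == "down"]

    @property
    def signature_strands(self) -> list[str]:
        out = []
        for p in self.down_pairs:
            out += [f"{p.precursor_id}-5p", f"{p.precursor_id}-3p"]
        return out

    def dependency_genes(self) -> set[str]:
        genes: set[str] = set()
        for pair in self.down_pairs:
            for arm in ("5p", "3p"):
                genes |= set(self.planted_targets.get(f"{pair.precursor_id}-{arm}", {}))
        return genes

    def affected_lineages(self) -> set[str]:
        out: set[str] = set()
        for pair in self.down_pairs:
            out |= set(pair.affected_cancers)
        return out

    def to_json(self, path) -> None:
        payload = {
            "planted_pairs": [asdict(p) for p in self.planted_pairs],
            "planted_targets": self.planted_targets,
            "planted_pathway": self.planted_pathway,
            "up_pathway": self.up_pathway,
            "dependency_effect": self.dependency_effect,
            "survival_effect": self.survival_effect,
            "confounder_effects": {
                g: list(v) for g, v in self.confounder_effects.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_pairs=[PlantedPair(**p) for p in d["planted_pairs"]],
            planted_targets=d["planted_targets"],
            planted_pathway=d["planted_pathway"],
            up_pathway=d["up_pathway"],
            dependency_effect=d["dependency_effect"],
            survival_effect=d["survival_effect"],
            confounder_effects={
                g: tuple(v) for g, v in d["confounder_effects"].items()
            },
        )


@dataclass
class Cohort:
    config: SimulationConfig
    mirna: dict[str, ExpressionStudy]
    mrna: dict[str, ExpressionStudy]
    network: TargetNetwork
    pathways: dict[str, set[str]]
    covariates: dict[str, CovariateMatrices]
    truth: GroundTruth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion) counts with var = mean + phi * mean^2."""
    if not np.all(np.isfinite(mean)) or np.any(mean <= 0):
        raise ValueError("NB means must be positive and finite")
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_cohort(config: SimulationConfig | None = None, seed: int = 0) -> Cohort:
    """Generate the full multi-cancer cohort with planted ground truth."""
    config = config or SimulationConfig()
    root = np.random.SeedSequence(seed)
    rng_setup, rng_mirna, rng_mrna, rng_cov = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]

    precursors = [f"mir-{i + 1:03d}" for i in range(config.n_precursors)]
    paired_mature = [f"{p}-{arm}" for p in precursors for arm in ("5p", "3p")]
    singletons = [
        f"mir-{config.n_precursors + i + 1:03d}-5p" for i in range(config.n_singletons)
    ]
    mature_ids = paired_mature + singletons
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    cancers = config.cancers

    # pathways: P01 is the planted "cell-cycle-like" set, P02 hosts the
    # up-pair targets, the rest are random draws
    pathways: dict[str, set[str]] = {}
    shuffled = list(genes)
    rng_setup.shuffle(shuffled)
    pathways["P01"] = set(shuffled[: config.pathway_size])
    pathways["P02"] = set(shuffled[config.pathway_size : 2 * config.pathway_size])
    for i in range(2, config.n_pathways):
        pathways[f"P{i + 1:02d}"] = set(
            rng_setup.choice(genes, size=config.pathway_size, replace=False)
        )

    truth = _plant_truth(config, precursors, genes, pathways, rng_setup)
    network = _build_network(config, mature_ids, genes, truth, rng_setup)

    base_mature = np.exp(rng_setup.normal(np.log(200.0), 1.0, size=len(mature_ids)))
    base_gene = np.exp(rng_setup.normal(np.log(150.0), 1.0, size=len(genes)))
    gene_length_kb = np.exp(rng_setup.normal(np.log(2.0), 0.5, size=len(genes)))

    planted_fold = {
        (p.precursor_id, c): p.log2fc if c in p.affected_cancers else 0.0
        for p in truth.planted_pairs
        for c in cancers
    }
    planted_set = {p.precursor_id for p in truth.planted_pairs}

    mirna_studies: dict[str, ExpressionStudy] = {}
    mrna_studies: dict[str, ExpressionStudy] = {}
    covariates: dict[str, CovariateMatrices] = {}
    for cancer in cancers:
        samples = [f"{cancer}_T{i + 1:02d}" for i in range(config.n_tumor)] + [
            f"{cancer}_N{i + 1:02d}" for i in range(config.n_normal)
        ]
        groups = pd.Series(
            ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
            index=samples,
        )
        is_tumor = np.array([g == "tumor" for g in groups])

        mi_study = _simulate_mirna_study(
            config, cancer, samples, groups, is_tumor, mature_ids, precursors,
            singletons, base_mature, planted_fold, planted_set, rng_mirna,
        )
        mirna_studies[cancer] = mi_study

        cov = _simulate_covariates(config, genes, mi_study.tumor_samples, rng_cov)
        covariates[cancer] = cov

        mrna_studies[cancer] = _simulate_mrna_study(
            config, cancer, samples, groups, is_tumor, genes, base_gene,
            gene_length_kb, truth, mi_study, cov, rng_mrna,
        )

    return Cohort(
        config=config,
        mirna=mirna_studies,
        mrna=mrna_studies,
        network=network,
        pathways=pathways,
        covariates=covariates,
        truth=truth,
    )


def _plant_truth(config, precursors, genes, pathways, rng) -> GroundTruth:
    planted_pairs = []
    cancers = config.cancers
    idx = 0
    for direction, count, sign in (
        ("down", config.n_planted_down, -1.0),
        ("up", config.n_planted_up, +1.0),
    ):
        for _ in range(count):
            planted_pairs.append(
                PlantedPair(
                    precursor_id=precursors[idx],
                    direction=direction,
                    log2fc=sign * config.pair_log2fc,
                    affected_cancers=cancers[: config.affected_cancers],
                )
            )
            idx += 1

    planted_targets: dict[str, dict[str, float]] = {}
    non_pathway_pool = [
        g for g in genes if g not in pathways["P01"] and g not in pathways["P02"]
    ]
    rng.shuffle(non_pathway_pool)
    pool_cursor = 0
    for pair in planted_pairs:
        pw = pathways["P01"] if pair.direction == "down" else pathways["P02"]
        pw_genes = sorted(pw)
        n_pw = config.pathway_targets_per_strand
        n_out = config.targets_per_strand - n_pw
        overlap_pw = max(config.cotarget_overlap // 2, 0)
        overlap_out = config.cotarget_overlap - overlap_pw
        pick_pw = list(rng.choice(pw_genes, size=2 * n_pw - overlap_pw, replace=False))
        t5_pw = pick_pw[:n_pw]
        t3_pw = pick_pw[n_pw - overlap_pw :]
        n_need = 2 * n_out - overlap_out
        pick_out = non_pathway_pool[pool_cursor : pool_cursor + n_need]
        pool_cursor += n_need
        t5 = t5_pw + pick_out[:n_out]
        t3 = t3_pw + pick_out[n_out - overlap_out :]
        planted_targets[f"{pair.precursor_id}-5p"] = {
            g: config.beta_mir for g in sorted(t5)
        }
        planted_targets[f"{pair.precursor_id}-3p"] = {
            g: config.beta_mir for g in sorted(t3)
        }

    planted_gene_set = {
        g for targets in planted_targets.values() for g in targets
    }
    confounded = list(
        rng.choice(
            genes, size=min(config.n_confounded_genes, len(genes)), replace=False
        )
    )
    confounder_effects = {g: (config.beta_dm, config.beta_cnv) for g in sorted(confounded)}
    # make sure a share of planted targets is genuinely confounded too
    for g in sorted(planted_gene_set)[:: 4]:
        confounder_effects[g] = (config.beta_dm, config.beta_cnv)

    return GroundTruth(
        planted_pairs=planted_pairs,
        planted_targets=planted_targets,
        planted_pathway="P01",
        up_pathway="P02",
        dependency_effect=config.dependency_effect,
        survival_effect=config.survival_hr,
        confounder_effects=confounder_effects,
    )


def _build_network(config, mature_ids, genes, truth, rng) -> TargetNetwork:
    rows = []
    for mature_id, targets in truth.planted_targets.items():
        for g in targets:
            n_src = 1 + rng.integers(0, len(SOURCES))
            src = ";".join(sorted(rng.choice(SOURCES, size=n_src, replace=False)))
            rows.append((mature_id, g, src))
    planted_edges = {(m, g) for m, g, _ in rows}
    for mature_id in mature_ids:
        decoys = rng.choice(genes, size=config.decoy_targets, replace=False)
        for g in decoys:
            if (mature_id, g) in planted_edges:
                continue
            src = str(rng.choice(SOURCES))
            rows.append((mature_id, g, src))
    edges = pd.DataFrame(rows, columns=["mature_id", "gene_id", "sources"])
    edges = edges.drop_duplicates(["mature_id", "gene_id"]).sort_values(
        ["mature_id", "gene_id"]
    )
    return TargetNetwork(edges=edges.reset_index(drop=True))


def _simulate_mirna_study(
    config, cancer, samples, groups, is_tumor, mature_ids, precursors,
    singletons, base_mature, planted_fold, planted_set, rng,
) -> ExpressionStudy:
    n_samples = len(samples)
    lib = np.exp(rng.normal(0.0, config.library_log_sd, size=n_samples))

    # shared per-(precursor, cancer) tumor fold; arm-specific jitter
    fold = {}
    for p in precursors + [s[:-3] for s in singletons]:
        if p in planted_set:
            shared = planted_fold[(p, cancer)]
        else:
            shared = rng.normal(0.0, config.shared_fold_log2_sd)
        fold[p] = shared
    log2mu = np.zeros((len(mature_ids), n_samples))
    # per-sample latent abundance shared by both arms of a precursor;
    # iteration order must be deterministic (dict, not set) so draws are
    # reproducible across processes
    latents = {
        p: rng.normal(0.0, config.latent_log2_sd, size=n_samples)
        for p in dict.fromkeys(m[:-3] for m in mature_ids)
    }
    for i, m in enumerate(mature_ids):
        p = m[:-3]
        arm_jitter = rng.normal(0.0, config.arm_noise_log2_sd)
        effect = fold[p] + arm_jitter
        log2mu[i] = np.log2(base_mature[i]) + latents[p] + effect * is_tumor
    mu = (2.0**log2mu) * lib[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=mature_ids, columns=samples)
    norm = counts_df / counts_df.sum(axis=0) * 1e6  # RPM
    return ExpressionStudy(
        cancer_type=cancer,
        raw_counts=counts_df,
        normalized=norm,
        feature_kind="miRNA",
        sample_groups=groups,
    )


def _simulate_covariates(config, genes, tumor_samples, rng) -> CovariateMatrices:
    n = len(tumor_samples)
    meth = rng.beta(2.0, 5.0, size=(len(genes), n))
    cnv_discrete = rng.choice([-1, 0, 1], size=(len(genes), n), p=[0.15, 0.7, 0.15])
    cnv = cnv_discrete + rng.normal(0.0, 0.1, size=(len(genes), n))
    return CovariateMatrices(
        methylation=pd.DataFrame(meth, index=genes, columns=list(tumor_samples)),
        copy_number=pd.DataFrame(cnv, index=genes, columns=list(tumor_samples)),
    )


def _simulate_mrna_study(
    config, cancer, samples, groups, is_tumor, genes, base_gene,
    gene_length_kb, truth, mirna_study, cov, rng,
) -> ExpressionStudy:
    n_samples = len(samples)
    gene_index = {g: i for i, g in enumerate(genes)}
    lib = np.exp(rng.normal(0.0, config.library_log_sd, size=n_samples))

    log2mu = np.tile(np.log2(base_gene)[:, None], (1, n_samples))

    # mild background DE on a random subset of genes
    n_bg = int(config.background_de_fraction * len(genes))
    if n_bg and config.background_de_sd > 0:
        bg_genes = rng.choice(len(genes), size=n_bg, replace=False)
        bg_eff = rng.normal(0.0, config.background_de_sd, size=n_bg)
        log2mu[bg_genes] += np.outer(bg_eff, is_tumor)

    # miRNA coupling: beta_miR * standardized log2 miRNA expression
    z_cache: dict[str, np.ndarray] = {}
    for mature_id, targets in truth.planted_targets.items():
        if mature_id not in z_cache:
            expr = np.log2(
                mirna_study.normalized.loc[mature_id, samples].to_numpy() + 1.0
            )
            sd = expr.std()
            z_cache[mature_id] = (expr - expr.mean()) / (sd if sd > 0 else 1.0)
        z = z_cache[mature_id]
        for g, beta in targets.items():
            log2mu[gene_index[g]] += beta * z

    # confounders act in tumor samples (centered, so group means stay put)
    tumor_cols = [s for s, t in zip(samples, is_tumor) if t]
    meth = cov.methylation
    cnv = cov.copy_number
    tumor_mask = np.where(is_tumor)[0]
    for g, (b_dm, b_cnv) in truth.confounder_effects.items():
        gi = gene_index[g]
        x_dm = meth.loc[g, tumor_cols].to_numpy()
        x_cnv = cnv.loc[g, tumor_cols].to_numpy()
        log2mu[gi, tumor_mask] += b_dm * (x_dm - x_dm.mean()) + b_cnv * (
            x_cnv - x_cnv.mean()
        )

    mu = (2.0**log2mu) * lib[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    norm = counts_df.div(counts_df.sum(axis=0) / 1e6, axis=1).div(
        gene_length_kb, axis=0
    )  # RPKM-style
    return ExpressionStudy(
        cancer_type=cancer,
        raw_counts=counts_df,
        normalized=norm,
        feature_kind="mRNA",
        sample_groups=groups,
    )


def simulate_dependency(
    truth: GroundTruth,
    genes,
    lineages,
    platform: str,
    lines_per_lineage: int = 12,
    effect: float | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> DependencyMatrix:
    """One dependency screen: planted target genes score low in affected
    lineages, everything else is noise around zero."""
    if noise_sd <= 0:
        raise ValueError("noise sd must be positive")
    effect = truth.dependency_effect if effect is None else effect
    platform_tag = int.from_bytes(platform.encode()[:4].ljust(4, b"\0"), "big")
    rng = np.random.default_rng(np.random.SeedSequence((seed, platform_tag)))
    genes = list(genes)
    dep_genes = truth.dependency_genes()
    affected = truth.affected_lineages()
    cols, lineage_map = [], {}
    score_cols = []
    for lineage in lineages:
        for i in range(lines_per_lineage):
            line = f"{lineage}_{platform}_L{i + 1:02d}"
            cols.append(line)
            lineage_map[line] = lineage
            col = rng.normal(0.0, noise_sd, size=len(genes))
            if lineage in affected and effect:
                hit = np.array([g in dep_genes for g in genes])
                col[hit] -= effect
            score_cols.append(col)
    scores = pd.DataFrame(
        np.column_stack(score_cols) if score_cols else np.empty((len(genes), 0)),
        index=genes,
        columns=cols,
    )
    return DependencyMatrix(
        scores=scores, platform=platform, lineage=pd.Series(lineage_map)
    )


def simulate_survival(
    signature_scores: pd.Series,
    true_hr: float,
    censoring_rate: float = 0.3,
    seed: int = 0,
    baseline_median_months: float = 60.0,
) -> pd.DataFrame:
    """Clinical table with hazard lambda0 * HR^z, z = standardized signature.

    ``true_hr`` is the hazard ratio per +1 SD of the signature (HR < 1:
    high signature protective).  Censoring is independent exponential
    tuned so roughly ``censoring_rate`` of records censor; age, grade
    and stage are generated as effect-free covariates.
    """
    if true_hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not (0 <= censoring_rate < 1):
        raise ValueError("censoring rate must be in [0, 1)")
    scores = signature_scores.dropna()
    if scores.empty:
        raise ValueError("empty signature score vector")
    rng = np.random.default_rng(seed)
    z = (scores - scores.mean()) / (scores.std() if scores.std() > 0 else 1.0)
    lam0 = np.log(2.0) / baseline_median_months
    lam = lam0 * true_hr**z.to_numpy()
    t_event = rng.exponential(1.0 / lam)
    if censoring_rate > 0:
        lam_c = lam0 * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=scores.size)
    else:
        t_cens = np.full(scores.size, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "time_months": np.maximum(time, 1e-3),
            "event": event,
            "age": np.round(rng.normal(62.0, 10.0, size=scores.size), 1),
            "grade": rng.choice([1, 2, 3], size=scores.size),
            "stage": rng.choice(["early", "late"], size=scores.size),
            "signature": scores.to_numpy(),
        },
        index=scores.index.rename("patient_id"),
    )


def simulate_perturbation(
    cohort: Cohort,
    mature_id: str,
    effect: float = 1.0,
    replicates: int = 3,
    seed: int = 0,
    dispersion: float = 0.05,
) -> ExpressionStudy:
    """Mimic-vs-control transfection profile for one planted miRNA.

    Target genes are downshifted by ``effect * |beta|`` log2 units in
    the mimic arm; counts carry triplicate-style NB noise.  The mimic
    samples occupy the ``tumor`` group slot and controls the ``normal``
    slot so the DE machinery applies unchanged.
    """
    if mature_id not in cohort.truth.planted_targets:
        raise KeyError(f"{mature_id!r} is not a planted miRNA")
    rng = np.random.default_rng(seed)
    genes = list(cohort.mrna[cohort.config.cancers[0]].features)
    base = np.exp(rng.normal(np.log(300.0), 1.0, size=len(genes)))
    targets = cohort.truth.planted_targets[mature_id]
    shift = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g in targets:
            shift[i] = -effect * abs(targets[g])
    samples = [f"mimic_{i + 1}" for i in range(replicates)] + [
        f"control_{i + 1}" for i in range(replicates)
    ]
    groups = pd.Series(["tumor"] * replicates + ["normal"] * replicates, index=samples)
    is_mimic = np.array([g == "tumor" for g in groups])
    log2mu = np.log2(base)[:, None] + np.outer(shift, is_mimic)
    lib = np.exp(rng.normal(0.0, 0.1, size=len(samples)))
    counts = _nb_draw(rng, (2.0**log2mu) * lib[None, :], dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    norm = counts_df / counts_df.sum(axis=0) * 1e6
    return ExpressionStudy(
        cancer_type="perturbation",
        raw_counts=counts_df,
        normalized=norm,
        feature_kind="mRNA",
        sample_groups=groups,
    )
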