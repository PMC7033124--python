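# strandcoop

Pan-cancer analysis of cooperating miRNA 5p/3p strand pairs.

Every precursor miRNA hairpin yields two mature strands — the 5p and 3p
arms — with different seed sequences and therefore different mRNA
targets. Historically one strand was treated as the functional product
and the other as a degraded passenger, which left half of the mature
miRNA repertoire unexamined. `strandcoop` implements a multi-stage
statistical framework for asking whether the *two strands of the same
precursor act together* in cancer: whether they are concordantly
dysregulated in tumors across cancer types, whether their target sets
jointly associate with cancer-cell survival/growth in genome-scale
RNAi/CRISPR dependency screens, whether they coordinately regulate the
same pathways by hitting complementary genes, and whether their combined
expression is prognostic for patient survival.

The package is aimed at computational cancer biologists who want each
stage as a reusable, tested library function, and at methodologists who
want a fully synthetic test bed: a built-in generator produces complete
multi-cancer cohorts (counts, networks, pathways, covariates, dependency
screens, clinical tables) with planted ground truth, so the whole
pipeline runs end-to-end and is measurable without any external data.

## The statistical core

- **Differential expression** — negative-binomial exact tests on raw
  counts (var = μ + φμ², TMM normalization, common dispersion φ̂ by
  conditional maximum likelihood), BH correction, and fold-change calls:
  miRNA at ≥1.5-fold, mRNA at ≥2-fold, both with BH *P* < 0.05.
  Features require normalized expression ≥1 in ≥50% of samples.
- **Strand concordance** — per-pair Spearman ρ of 5p vs 3p expression
  against random cross-precursor background pairs (Wilcoxon rank-sum),
  pooled fold-change concordance over (pair, cancer) rows, and the
  pan-cancer rules: concordant dysregulation in ≥5 cancer types, with
  downregulation at least twice as frequent as upregulation.
- **Target network** — union of prediction/curation sources, filtered
  per cancer to edges with inverse DE calls (miRNA down ⇒ gene up or
  vice versa) and negative Spearman correlation at BH *P* < 0.05.
- **Dependency screens** — per cell line, genes ranked by knockdown
  viability score; each miRNA's target set scored by permutation GSEA
  (weighted Kolmogorov–Smirnov ES, gene-sampling null, NES, sign-
  stratified FDR). A significantly negative NES (FDR < 0.1) marks the
  miRNA as a survival/growth modulator of that line. Calls aggregate to
  strand co-association fractions and a two-platform pair selection with
  a <1.5-fold strand-balance annotation.
- **Pathway coordination** — hypergeometric ORA of strand targets, a
  10,000-random-pair correlation null (one-sided Wilcoxon, BH *P* <
  10⁻³), the coordination score |prop₅ₚ − prop₃ₚ| < 0.5, co-targeting
  fractions, and recurrence ≥50% across the pair's concordant cancers.
- **Confounder-adjusted regression** — per (gene, miRNA, cancer) OLS
  `Y = β₀ + β_DM·x_DM + β_CNV·x_CNV + β_miR·x_miR`, with rank-product
  meta-analysis (column-permutation *P*, BH) for recurrent inverse
  associations across cancers, plus a Kolmogorov–Smirnov essential-gene
  depletion check against perturbation profiles.
- **Survival signature** — per-patient mean log₂ expression of the four
  mature strands, quartile stratification, Kaplan–Meier/log-rank on
  Q1 vs Q4 with 10-year truncation, and Newton–Raphson Cox regression
  (Breslow ties) for univariate and covariate-adjusted hazard ratios.

## Worked example

```python
from strandcoop import SimulationConfig, simulate_cohort
from strandcoop.diffexpr import differential_expression
from strandcoop.concordance import (
    pair_strands, build_pair_dysregulation, foldchange_concordance,
)
import pandas as pd

sim = SimulationConfig(n_cancers=4, affected_cancers=3, n_genes=600,
                       n_precursors=20, n_singletons=20, n_pathways=8,
                       pathway_size=30, targets_per_strand=25,
                       pathway_targets_per_strand=15, cotarget_overlap=6,
                       n_confounded_genes=80)
cohort = simulate_cohort(sim, seed=42)

mirna_de = {c: differential_expression(cohort.mirna[c]) for c in sim.cancers}
pairs, _ = pair_strands(list(cohort.mirna["C1"].features))
dys = [build_pair_dysregulation(p, mirna_de, min_cancers=3) for p in pairs]

rows = [{"log2fc_5p": r["log2fc_5p"], "log2fc_3p": r["log2fc_3p"]}
        for d in dys for _, r in d.per_cancer.iterrows()]
rho = foldchange_concordance(pd.DataFrame(rows))
print(f"5p/3p fold-change concordance: rho = {rho.rho:.2f} "
      f"(p = {rho.p_value:.2e}, n = {rho.n})")
pan = [d for d in dys if d.pan_cancer]
print(f"pan-cancer concordant pairs: {[d.pair.precursor_id for d in pan]}")
print(pan[0].per_cancer.round(2))
```

prints

```
5p/3p fold-change concordance: rho = 0.72 (p = 4.43e-14, n = 80)
pan-cancer concordant pairs: ['mir-001', 'mir-002', 'mir-003']
    log2fc_5p  log2fc_3p call_5p call_3p
C1      -1.33      -1.38    down    down
C2      -2.09      -1.91    down    down
C3      -1.60      -1.81    down    down
C4      -0.56       0.13      ns      ns
```

The fold changes of the two arms of each precursor track each other
(ρ = 0.72 pooled over all pairs and cancers), and the three planted
pairs — concordantly shifted in three of the four simulated cancers —
are exactly the ones flagged pan-cancer. `mir-001`'s table shows both
strands called "down" in the affected cancers C1–C3 and non-significant
in the unaffected C4.

The full pipeline (all eight stages, writing TSV/JSON reports) runs as

```bash
strandcoop all --simulate --seed 7 --out-dir out/
```

and is deterministic: the same seed reproduces byte-identical reports.

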