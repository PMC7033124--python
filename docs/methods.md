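# Methods

This note documents the statistical models, defaults, and design
choices behind `strandcoop`, in the order the pipeline runs them.

## Differential expression (`strandcoop.diffexpr`)

Counts are modeled as negative binomial with a mean–dispersion
parameterization, var = μ + φμ², shared with the synthetic generator so
the dispersion estimate is directly comparable to the generating value.
The analysis path is the classic exact-test one:

1. **Expression filter.** A feature is analyzed only if its normalized
   expression (RPM for miRNA, RPKM-style for mRNA) is ≥ 1 in at least
   ⌈0.5·n⌉ samples. The filter runs on the normalized matrix first;
   testing then uses raw counts of the surviving features.
2. **TMM normalization.** Trimmed mean of M-values with the standard
   trims (30% on log-ratios, 5% on average abundance),
   precision-weighted mean, reference column chosen as the sample whose
   upper-quartile expression is closest to the mean upper quartile, and
   factors rescaled to geometric mean 1. The implementation is verified
   against an independent reference implementation to 1e-6 on a frozen
   fixture.
3. **Pseudo-counts.** Before dispersion estimation and testing, each
   sample's counts are scaled to the geometric-mean *effective* library
   size (library size × TMM factor). This simple scaling replaces the
   full quantile-adjustment scheme; it is exact in the equal-library
   limit, and the exact test built on it reproduces the closed-form
   binomial limit to 1e-10 (tested).
4. **Common dispersion.** φ̂ maximizes the conditional NB likelihood
   (conditioning each feature on its group total removes the mean
   parameter) over a log-spaced grid refined by bounded golden-section
   search on log φ. If the Poisson limit fits at least as well, φ̂ = 0.
   Only a single common dispersion is estimated — no tagwise shrinkage —
   which keeps the estimator fully testable by parameter recovery.
5. **Exact test.** For each feature the tumor-total z₁ given the total
   z = z₁+z₂ follows a negative hypergeometric law with shape n₁/φ and
   n₂/φ (binomial when φ = 0). The two-sided p sums the probabilities of
   all outcomes at most as probable as the observed split (relative
   tolerance 1e-10 for ties). Zero totals give p = 1. Group totals are
   rounded after pseudo-count scaling.
6. **Calls.** BH-adjusted p < 0.05 and |log₂FC| ≥ log₂(1.5) for miRNA or
   log₂(2) for mRNA. Fold changes are computed on normalized means with
   a 0.5 pseudo-count to stabilize zeros (recorded in the config).

Testing is unpaired; the tumor/normal columns are treated as independent
groups.

Spearman correlations use average-rank ties with the t approximation,
switching to the exact permutation distribution for n ≤ 9. Constant
vectors are flagged invalid rather than given an arbitrary ρ.

## Strand concordance (`strandcoop.concordance`)

Arms pair only when both 5p and 3p mature ids of a precursor are
present; singletons are reported separately. Two complementary
concordance views are exposed:

- **Expression correlation**: per-pair Spearman ρ across samples within
  a cohort, contrasted against random cross-precursor pairs (default
  background size 10× the true pairs — the background size for this
  contrast is a package choice; the analysis uses it only descriptively)
  with a two-sided Wilcoxon rank-sum test (exact for m+n ≤ 20, tie-
  corrected normal approximation otherwise).
- **Fold-change concordance**: a single Spearman ρ over all (pair,
  cancer) rows pooled, irrespective of significance. Pooling rows rather
  than averaging per-cancer correlations matches the one-dot-per-
  pair-per-cancer convention.

"Concordant dysregulation" in one cancer requires *both* strands to pass
the fold/significance rule with the same sign. Pan-cancer selection
requires ≥ 5 concordant cancers (`min_cancers`), and the
downregulation-bias rule selects miRNA whose "down" calls are at least
twice (`down_up_bias`) as frequent as their "up" calls. Selection is
monotone: adding a concordant cancer can never remove a pair.

## Target network (`strandcoop.network`)

The base network is the union of any number of source tables (e.g.
sequence-based predictors plus a curated database); provenance is the
set of contributing sources per edge. Cancer-specific filtering retains
an edge iff the DE calls are opposite ((down, up) or (up, down)) *and*
Spearman ρ < 0 with BH-adjusted correlation p < 0.05, the BH family
being all DE-consistent candidate edges of that cancer. Correlations use
all samples (tumor + normal pooled) by default — pooling maximizes the
dynamic range that drives the inverse association — with a `tumor_only`
switch for the stricter alternative; which sample set the original
analyses used is not derivable, so both are available.

## Enrichment core (`strandcoop.enrichment`)

The weighted Kolmogorov–Smirnov enrichment score uses hit increments
|metric|^p / Σ|metric|^p (default exponent p = 1; p = 0 gives the
unweighted statistic) and miss decrements 1/(N−N_H). The implementation
evaluates only the 2k candidate extrema (just before and just after
each hit), which is algebraically identical to the O(N) running sum
(asserted against a naive oracle to 1e-12) and lets thousands of
permutations run vectorized. Ties in the ranking metric are broken
lexicographically by gene id, so results are order-independent.

Significance uses **gene-sampling permutation**: null ES from random
same-size gene subsets of the ranked list. Phenotype permutation is
impossible here because each dependency screen supplies exactly one
ranked list per cell line. NES divides ES by the mean |null ES| of
matching sign; p is the same-sign tail fraction; FDR follows the
sign-stratified ratio-of-tails procedure with null NES pooled across
the evaluated collection. Null draws are cached per set size within one
ranked list. An exhaustive mode enumerates all C(N, k) subsets for
small instances and is used by the oracle tests.

**ssGSEA** ranks a single sample's genes (descending, ties by id) and
scores Σᵢ (weighted in-set ECDF − out-set ECDF) with weight
(N−i)^α at position i (α = 0.25), divided by N. The constant
normalizer is a deliberate choice: dividing by the range of the running
difference (a per-profile normalizer) would break two contracts this
package tests — that the top-k expressed set is maximal among size-k
sets, and that raising in-set expression never lowers the score. The
statistic is rank-based and hence invariant to monotone transforms.

Over-representation uses the upper-tail hypergeometric law
P(X ≥ overlap) with the universe restricted to measured, pathway-
annotated genes.

## Dependency screens (`strandcoop.depscreen`)

Genes are ranked per cell line by viability/growth score, descending,
so the genes the line depends on (low scores) sit at the bottom; a
miRNA's cancer-specific target set with significantly negative NES
(FDR < 0.1) marks that miRNA as a potential survival/growth brake for
the line. Gene sets are restricted to 10–500 members (standard GSEA
practice; configurable). Lineage-to-cohort matching is an explicit map,
never inferred from names, and each cancer's network is evaluated only
in matched-lineage lines.

Two association denominators are reported deliberately: the per-miRNA
**association fraction** uses all screened lines of the relevant
cancers, while the **co-association fraction** of a pair uses only
lines where at least one strand associates. The final pair selection
requires pan-cancer concordant downregulation, both strands associated
on both platforms, and annotates the larger/smaller strand association
ratio; ratios < 1.5 are flagged "balanced" (both strands carry
comparable weight).

## Pathway coordination (`strandcoop.pathways`)

For each pan-cancer pair and each of its concordant cancers, ORA runs
for the 5p, 3p and combined target queries; a pathway counts as
associated when the combined query is enriched (BH p < 0.05). Three
filters then gate high confidence:

1. **Correlation null**: the pair's edge correlations to the pathway
   must be more negative than 10,000 random (miRNA, gene) pairs of that
   cancer (one-sided Wilcoxon; BH over all pair–pathway–cancer tests;
   adjusted p < 10⁻³). The random draw happens once per cancer and is
   reused across tests. Fewer than 3 edges fails closed.
2. **Coordination score**: | |T₅∩P|/|P| − |T₃∩P|/|P| | < 0.5, with the
   denominator restricted to pathway genes measured in that cancer
   (unmeasured genes cannot appear in the network, so counting them
   would deflate both proportions).
3. **Recurrence**: the association must reappear in ≥ 50% of the
   cancers where the pair is concordantly dysregulated.

The co-targeting fraction of a pathway is |T₅∩T₃∩P| / |(T₅∪T₃)∩P| —
the Jaccard of the strand target sets restricted to P — averaged over
the pair's coordinated pathway pool; a pathway-size denominator is
available behind a flag but the union denominator is the default
reading of "fraction of co-targets in the pool".

Sample stratification splits each strand at its median over tumor
samples: both below → "low", both at/above → "high", else "mixed";
per-gene median log₂ fold changes (vs the normal-sample mean) are
reported per group. The activation comparison scores a pathway per
tumor sample by ssGSEA, splits samples at the top/bottom activation
quartile (configurable), and tests per strand whether expression is
lower in high-activation samples (one-sided rank-sum; BH across
strands × cancers by the caller).

## Regression and recurrence (`strandcoop.regression`)

Per (gene, miRNA, cancer): OLS of Y = log₂(normalized mRNA + 1) on the
tumor samples against methylation, copy number and miRNA expression,
all standardized within the cancer so β_miR is comparable across
cancers before ranking. Inference on β_miR is a two-sided t test with
n−4 df; design matrices with condition number > 1e8 are flagged
collinear and excluded. BH runs within each cancer.

The rank product collates β_miR across cancers: ranks 1 = most negative
(inverse direction; the positive direction is computed symmetrically
but only inverse associations feed the recurrence list), RP = geometric
mean of a row's available ranks. The permutation p shuffles each
column's ranks independently among its observed rows (Monte Carlo,
default 10,000 draws; capped at 2,000 inside the full pipeline run for
runtime, recorded in the report) and compares each row only against
null rows sharing its missingness pattern, so rows observed in k < 14
cancers are calibrated against their own k. An exhaustive mode
enumerates all per-column permutations for tiny matrices and anchors
the oracle test. The Monte Carlo estimator was chosen over the gamma
approximation precisely because it is exactly verifiable by
enumeration.

The essential-gene depletion check is a two-sided two-sample KS test
comparing perturbation log₂ fold changes of a miRNA's essential-gene
targets against all remaining measured genes, plus the directional
median shift.

## Survival signature (`strandcoop.survival`)

The signature is the per-patient mean of log₂(normalized + 1) across
the four strands; averaging on the log scale prevents one abundant
strand from dominating the mean (raw-scale averaging is available via
`log_scale=False`). Patients are ranked and split into four near-equal
quartiles (deterministic: ties broken by patient id; sizes differ by at
most one). Follow-up is truncated at 120 months (10 years): later
times become censored observations at the horizon.

Kaplan–Meier is the product-limit estimator; the median is the first
time S(t) ≤ 0.5. The log-rank test uses the hypergeometric variance
with a 1-df chi-square. The Cox model maximizes the partial likelihood
by Newton–Raphson with step-halving (≤ 50 iterations, centered
covariates); ties use the Breslow approximation by default with Efron
behind `ties="efron"`. Monotone likelihood (runaway coefficient or
exploded standard error) is flagged rather than reported as an
estimate. The signature group enters as Q4 = 1 vs Q1 = 0, so HR < 1
means high expression is protective. In the pipeline's multivariate
fit, age is binarized at the cohort median, grade enters as an ordinal
numeric, and stage as early = 0 / late = 1.

The signature-variant comparison tests, across cancers, whether the
four-strand signature's −log₁₀ log-rank p values are larger than those
of single-strand and single-pair variants pooled (one-sided rank-sum).
Which exact quantity such a cross-signature comparison should use is a
genuinely open design choice; comparing −log₁₀ p across the same
cancers is the reading this package implements and tests.

## Synthetic cohorts (`strandcoop.simulate`)

The generator produces the statistical structure the pipeline assumes,
with every effect recorded in a `GroundTruth` object:

- **Counts**: NB(μ, φ = 0.15) with log-normal library sizes (sd 0.3 on
  the natural log), so normalization does real work. Base abundances
  are log-normal across features.
- **Strand coupling**: both arms of a precursor share a per-sample
  latent abundance (sd 0.5 log₂ units) — creating within-pair
  expression correlation that random cross-precursor pairs lack — and a
  shared per-cancer fold component (sd 0.35 log₂ for unplanted
  precursors, plus arm-specific jitter sd 0.15). The background sd is
  set so that pooled 5p/3p fold-change concordance stays high (ρ > 0.6)
  while unplanted precursors essentially never reach pan-cancer
  concordant significance, keeping the planted truth identifiable.
- **Planted pairs**: by default two precursors planted "down"
  (log₂FC −1.5) and one "up" (+1.5) in 6 of 8 cancers.
- **Targets**: each planted strand suppresses 40 genes
  (β_miR = −0.8 per SD of miRNA log-expression, acting on all samples
  through the realized miRNA expression, which yields inverse
  correlation, tumor/normal DE of the targets, and a recoverable
  regression coefficient), 20 of them inside the planted pathway; the
  two strands co-target 8 genes, giving pathway-restricted co-target
  fractions near 0.1. Methylation (Beta(2,5)) and copy number
  ({−1,0,1} + noise) act additively on the log scale in tumor samples
  (centered, so they confound the regression without shifting DE).
- **Dependency screens**: planted down-pair target genes shift by
  −1.0 (sd 0.3 noise) in cell lines of affected lineages; two platforms
  share the truth with independent noise.
- **Survival**: exponential times with hazard λ₀·HR^z, z the
  standardized four-strand signature, HR = 0.3 per SD, λ₀ set for a
  60-month baseline median, independent exponential censoring tuned to
  ≈ 30%. Age/grade/stage are generated effect-free.
- **Default shape**: 8 cancers × (30 tumor + 15 normal), 60 paired
  precursors + 80 singletons (200 mature miRNA), 2,000 genes, 20
  pathways × 50 genes, 12 cell lines per lineage and platform. A full
  pipeline run on this cohort takes on the order of a minute on one
  CPU; the test suite uses a further-reduced cohort for unit-level
  checks.

What the generator does **not** emulate: real per-cancer sample sizes
or miRNA abundance spectra, isoform/arm-switching, batch effects,
correlated censoring, copy-number segments spanning genes, or any
sequence-level structure (networks are planted, not predicted). Passing
tests therefore demonstrate correctness and calibration of the
machinery under the assumed generative model, not performance on real
tumor data.

## Numerical and degenerate-input conventions

- All randomness flows from integer seeds through spawned numpy
  generators; iteration orders are deterministic (no set-order
  dependence), so identical seeds give byte-identical reports across
  processes.
- BH adjustment delegates to `statsmodels`; Wilcoxon/hypergeometric/KS
  tests to `scipy.stats`.
- Degenerate inputs fail soft where the analysis can continue (empty
  filter results warn; all-tied rank-sum inputs give p = 1; a pair with
  no associated lines reports a missing fraction) and fail hard where
  silence would corrupt results (negative counts, duplicate edges,
  sample/metadata mismatches, zero-variance log-rank, non-positive
  dispersion or hazard ratios).

## Known limitations

- DE implements the exact-test path only: no tagwise dispersion, no
  GLM/quasi-likelihood path, no paired designs.
- The rank product's missing-data handling (ranking within observed
  rows, pattern-stratified null) is one defensible convention among
  several; k is recorded per row so users can filter.
- Cox fitting covers time-fixed covariates with Breslow/Efron ties;
  no stratification, time-varying covariates, or competing risks.
- The CLI runs on simulated cohorts (plus a clinical-TSV path for the
  survival stage); analyses of user-supplied cohorts use the library
  API, whose readers accept plain TSV/GMT throughout.
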