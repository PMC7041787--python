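# Methods

This note documents the statistical models implemented in `crossomics`,
the defaults and why they were chosen, what the synthetic corpus does and
does not emulate, and the numerical choices that affect results.

## Gene scoring from GWAS summary statistics

SNPs are assigned to genes whose body, extended by a window (default
20 kb, boundaries inclusive), covers the SNP position. Each SNP maps to at
most one gene: nearest gene body (distance zero inside the body), ties
broken lexicographically by gene id — a deterministic rule chosen because
assignment must not depend on input order. The per-gene statistic is the
best (minimum) assigned p-value, reported as −log₁₀ p, with the Šidák
adjustment 1 − (1 − p)ⁿ, the exact null distribution of the minimum of n
independent uniforms.

*Assumption and deliberate simplification*: independence of SNPs within a
gene. Linkage disequilibrium makes the effective number of tests smaller
than n, so the Šidák-adjusted p is conservative in LD-dense regions. An
LD-aware multi-SNP gene model is out of scope; the synthetic corpus
simulates association directly on the summary-statistic scale (noncentral
χ²(1, λ) tails at causal SNPs), where SNP independence holds by
construction. Gene-level "significance" means Bonferroni over the genes
tested at α = 0.05.

## Pathway enrichment and intersection

The set statistic is a one-sample Z of the pathway's mean gene score
against the population of all scored genes,
z = (x̄_set − x̄_all)/(sd_all/√m), with a one-sided upper-tail normal p.
Genes without a score are ignored, not imputed: coverage is sparse by
design, because each SNP feeds only one gene. FDR control is
Benjamini–Hochberg throughout ("q"). Shared pathways require q < q_cut
(default 0.1) in the anchor phenotype and in at least one (`any`) or every
(`all`) other phenotype. Phenotype similarity is the Pearson correlation of
enrichment-Z vectors over pathways present in all phenotypes.

The Z statistic is exactly location-invariant in the scores and its normal
p agrees with random-set permutation to within Monte-Carlo error for set
sizes ≥ ~20 (tested at m = 50).

## Pathway geometry

Pathway distance is Jaccard on gene sets, 1 − |A∩B|/|A∪B| (an overlap
coefficient is a config alternative). Embedding is classical Torgerson
scaling: double-center B = −½·J·D²·J, eigendecompose, take the top
positive eigenpairs; axes with non-positive eigenvalues are zero-filled,
and each axis is sign-oriented so its largest-magnitude coordinate is
positive (the embedding is otherwise defined only up to rotation and
reflection). scikit-learn's MDS is the SMACOF stress majorizer, a
different algorithm, which is why Torgerson scaling is implemented
directly. Clustering is average-linkage agglomerative on the distance
matrix, cut to exactly k clusters (default 5), labels renumbered by first
member index so the partition is input-order invariant.

## Permutation engine

Null sets are drawn uniformly without replacement. The p-value uses the
add-one convention p = (n_at_least + 1)/(n_iter + 1), which keeps p
strictly positive and matches the standard recommendation for Monte-Carlo
tests; "at least as extreme" is ≥. Default n_iter is 10⁴ in the pipeline
(10⁵–10⁶ via configuration). For pure overlap nulls the engine agrees with
the exact hypergeometric tail to ±0.01 at 10⁵ draws. Note that permutation
p-values inherit the granularity of the statistic: a coarse count
statistic yields lumpy (super-uniform, conservative) p-values; a
continuous statistic yields p-values uniform on the (n_iter+1)-point grid.

## Methylation analysis

Regression is on M-values, log₂(β/(1−β)) with β clamped to
[10⁻⁶, 1−10⁻⁶]: β proportions are heteroskedastic near 0 and 1 and the
log-odds transform stabilizes variance for OLS. The per-CpG model is
M ~ case + covariates (age, sex by default), two-sided t on the case
coefficient; with no covariates this reduces exactly to the
pooled-variance two-sample t-test. Zero-variance CpGs are flagged
untestable and excluded from the test count (a relative tolerance absorbs
float accumulation noise in genuinely constant rows). The family-wise
threshold is α/n_tests; with α = 0.05 and 8,236 loci this is
6.07 × 10⁻⁶.

The consistency test between two methylation gene lists is the two-sided
exact binomial under p₀ = ½ using the minimum-likelihood rule (sum of all
outcome probabilities no larger than the observed one), which equals the
doubled tail when p₀ = ½: for 34 consistent genes of 38 it gives
6.04 × 10⁻⁷, and for 124 of 149 a value below 2.2 × 10⁻¹⁶, the reporting
floor many statistical environments print. p₀ = ½ encodes "no
directional preference"; the convergence stages are (1) module genes ∩
smoking-methylation panel, (2) stage 1 with ≥ 2 pieces of curated support
(an input column, never re-derived), (3) members of each stage harboring
at least one Bonferroni-significant CpG.

## cis-QTL regression

Candidate pairs are all (SNP, feature) on the same chromosome within
20 kb (inclusive). Each pair is an additive-model OLS of the feature on
dosage (0/1/2 or fractional); covariates, when supplied, are projected out
of both sides first (Frisch–Waugh) with degrees of freedom reduced
accordingly. Monomorphic SNPs are skipped and reported. BH FDR is taken
across all tested pairs; the default significant set is FDR < 0.01. LD
expansion adds any same-chromosome SNP within a window whose dosage r²
with a tag reaches 0.5. The closed-form vectorized regression is
cross-checked against statsmodels OLS in the unit tests.

## Co-expression modules

The network is unsigned: a_ij = |cor(x_i, x_j)|^β, diagonal zero.
Topological overlap is
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), TOM_ii = 1,
which is provably in [0,1] for unsigned adjacency. Modules are
average-linkage clusters of 1 − TOM below a static height cut (default
0.9); clusters smaller than 30 genes are left unassigned (label 0). The
static cut is a deliberate simplification of dynamic tree cutting, so
module counts are not comparable to pipelines that use it. Eigengenes are
the first principal component of the module's standardized expression,
unit norm, sign-oriented so the mean gene–eigengene correlation is
non-negative. Hubs are the top 10 genes by intramodular connectivity
(summed adjacency to same-module genes), ties by gene id.

**Soft power selection.** The scale-free criterion picks the smallest
β ∈ 1..20 whose binned log-log connectivity fit reaches R² ≥ 0.8 with a
negative slope. Two guards proved necessary:

- a qualifying power must keep **median connectivity ≥ 1**. At large
  powers most adjacencies vanish; the connectivity histogram of a
  near-empty network is steeply decreasing and mimics a power law, so
  without the guard the criterion can "qualify" a power at which the
  network is unusable (most genes disconnected).
- when no power qualifies — the generic outcome for block-structured
  data, which is modular rather than scale-free — the fallback is the
  conventional default unsigned power **β = 6**, not the argmax-R² power:
  chasing R² on non-scale-free data drives β high enough to erase
  within-module adjacency entirely.

Region×stage profiles are per-module means over (region, stage) cells,
centered on the module grand mean; expression is assumed log₂ in files,
so a twofold linear-scale call is a spread ≥ 1 on the log₂ scale, applied
to region means and stage means separately.

## ANOVA screens and integration

The group screen is one-way ANOVA per gene (for two groups, F = t² of the
pooled t-test exactly); Tukey HSD pairwise comparisons are computed only
for genes passing ANOVA at α = 0.05 — the screen-then-compare order keeps
the post-hoc family small. The dose screen adds a monotone-trend sign from
the OLS slope of per-dose means on dose rank; "dose-dependent" is
operationalized as ANOVA significance plus that sign. Network enrichment
counts edges among the query genes and permutes equally sized node sets
from the supplied network (the network is an input; no database retrieval).

The evidence matrix joins all stage outputs by gene id. Boolean columns:
module membership, smoking methylation, disease methylation, cis-meQTL,
subnetwork membership (≥ 1 edge to another candidate), differential- and
drug-ANOVA significance at a configurable 0.05, and a literature flag
(always an input). evidence_count is the number of true booleans;
candidate = smoking methylation ∧ disease methylation, evaluated over the
evidence-filtered convergence stage; rows are ranked by evidence_count,
then gene id.

## Synthetic corpus

Defaults are a desk-scale analogue of the comorbidity study design:
2,000 genes on 20 chromosomes, 200 pathways of 10–60 genes, seven
phenotypes — one disease-like and four smoking-like sharing 8 causal
pathways (λ = 30 noncentrality at causal SNPs), one null (λ = 0), one
height-like with disjoint causal pathways — 200/200 methylation
cases/controls with a 150-gene smoking panel of which 125 genes carry a
case shift of Δ = 2 on the M-value scale (so the convergence stages show
the excess the design is about), age/sex covariate effects, 50 planted
cis pairs with slope 1 per allele, five 50-gene expression modules at
within-correlation 0.8 over a 4-region × 5-stage design (one module with
a 2.5-fold regional shift, one with a temporal shift), a four-group
case/control design with 9 differentially expressed genes, two drug dose
series in which candidates respond at 70% versus a 5% background rate,
and an Erdős–Rényi interaction network with dense wiring among
candidates. Effect sizes are calibration choices — the emulated study
reports none — fixed once at values a cohort of this size could plausibly
detect.

What the generator does **not** emulate: realistic LD maps (LD is a
two-SNP haplotype-copy model: the partner allele copies the tag allele
with probability ρ), cell-composition effects in methylation, batch or
surrogate structure, heavy-tailed expression noise, genome-scale test
counts, and pathway databases' nested redundancy. Passing tests therefore
demonstrate that each stage recovers the signal class it targets at
realistic desk-scale power, not that real cohorts would yield comparable
counts. One visible consequence of planted overlap: intersection stages
legitimately recover a few non-planted pathways that share genes with the
planted causal sets.

All randomness flows through numpy's PCG64 (`default_rng`); every
artifact derives its stream from (seed, component-code), so a fixed seed
reproduces the corpus byte-identically regardless of which artifacts are
built or in what order.

## Numerical choices

- p-values of 0 or > 1 in GWAS input are dropped, not clamped (the
  −log₁₀ transform must stay finite), and accounted for in load reports.
- Coordinates are 1-based inclusive in all files; converters are the only
  code allowed to do arithmetic on the convention.
- Pathway size bounds [10, 300] are inclusive.
- The Šidák adjustment uses `expm1`/`log1p` to keep precision for tiny p.
- MDS treats eigenvalues below 10⁻¹² as non-positive; a configuration
  with no positive eigenvalue raises a degenerate-input error.
- Linkage tie-breaks follow scipy's deterministic ordering; labels are
  canonicalized afterwards, so partitions are input-order invariant.
- Tests and the default pipeline use 10⁴ permutation draws; the engine
  accepts larger values where higher resolution is needed.

## Known limitations

Best-SNP + Šidák is conservative under LD and cannot reproduce LD-aware
gene counts; the static tree cut under-splits nested modules; the
scale-free criterion is uninformative on modular data (the β = 6 fallback
then decides); the evidence matrix treats curated support counts and
literature flags as trusted inputs; and acceptance-style recovery rates
are statements about the synthetic design, not about any particular
cohort.
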