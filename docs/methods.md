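# Methods

## The analysis model

### cis-eQTL mapping

For each gene the cis window is the gene body extended by `cis_window_bp`
(default 20 000 bp) on both sides; a SNP pairs with the gene iff its
distance to the gene body is ≤ the window, boundary inclusive, same
chromosome, strand ignored. Distance is 0 inside the gene body and the gap
to the nearest gene edge otherwise. The 20 kb default is the conservative
end of the cutoffs used in the cis-eQTL literature; most cis effects sit
close to their gene and false positives grow with distance.

Where several microarray probes map to one gene, the probe with the highest
sample variance is retained (exact ties break to the lexicographically
smallest probe id, so selection is deterministic). Known covariates can be
regressed out of every probe (OLS residuals on covariates + intercept)
before mapping; rank-deficient covariate matrices are rejected with the
collinear columns named.

Each pair is fit by ordinary least squares of expression on additive dosage
(0/1/2 minor-allele count) with an intercept, over the samples with an
observed dosage (complete-case per pair, no imputation — the slope stays
unbiased and the per-pair `n_used` is explicit). The slope's two-sided
t-test P-value (df = n_used − 2) is floored at 1e-300 against underflow.
Pairs with fewer than 4 usable samples or a monomorphic dosage are flagged
untested and excluded from multiple-testing correction; a run in which *no*
pair is testable is an error rather than an empty result.

Benjamini–Hochberg q-values are computed jointly across all tested cis
pairs (one genome-wide cis analysis, never per-gene):
`q_i = min_{p_j ≥ p_i} p_j · m / rank_j`, clipped at 1. Significance
everywhere means FDR < 0.05.

A light population-stratification screen replaces heavier eigen-analysis
machinery: dosages are mean-imputed, standardized and decomposed by SVD,
and each of the top `n_pcs` (default 10) genotype PCs is Pearson-correlated
with every probe; the report carries the minimum P per PC and the fraction
of probe tests below 0.05, which stays at ~0.05 in an unstructured cohort.

Per-SNP QC defaults: MAF ≥ 0.05, call rate ≥ 0.95, Hardy–Weinberg exact
P ≥ 1e-6 (the exact conditional heterozygote-count test). All three are
exposed as configuration.

### LD tools

LD is the squared Pearson correlation of dosages (composite, phase-free r²)
over pairwise-complete samples, requiring ≥ 4 complete pairs and
polymorphism on the joint subset; everything is computed from the supplied
genotypes, never a reference panel. Pruning is a greedy positional scan
(PLINK-style): a SNP is dropped iff its r² with an already-retained SNP
within 1 Mb exceeds the threshold. Both pruning and proxy lookup use a
*strict* r² > 0.8 rule — the proxy threshold is stated strictly, and using
the same convention for pruning keeps one boundary semantics; at threshold
1.0 nothing qualifies. Monomorphic SNPs are retained untested with a
warning. Pairwise r² over a chromosome is computed by masked matrix algebra
(zero-filled missing values with all moments accumulated over the
joint-presence mask), holding one chromosome's r² matrix in memory — fine
at the panel sizes this package targets.

### Replication

Analysis is restricted to the caller-prepared universe (SNPs present in
both studies, LD-pruned; gene identifiers already harmonized). A discovery
pair replicates if it is significant in the validation study, or if a proxy
of its SNP (r² > 0.8) is a significant validation eQTL for the *same* gene.
The relative replication ratio divides the replication percentage of
significant (FDR < 0.05) discovery pairs by that of non-significant pairs;
a zero denominator is flagged infinite, an empty stratum undefined.
Significance comes from B permutations drawing `n_sig` pairs uniformly
without replacement from the universe; since each universe pair carries a
fixed replicated flag, the permuted overlap count is exactly a
hypergeometric draw and is sampled as such (verified against explicit
subset draws in the tests). All permutation P-values in the package use the
add-one estimator (b + 1)/(B + 1), with the reportable bound "< 1/B" when
no permutation reaches the observed value.

### GWAS–eQTL enrichment

Forward direction: over the shared, LD-pruned SNP list (each SNP annotated
with its GWAS P and its minimum FDR across its cis genes), the fraction of
eQTL-significant SNPs among those with GWAS P ≤ t, for
t ∈ {1, 0.5, 0.1, 0.05, 0.01, 1e-3, 1e-4, 1e-5, 1e-6}, divided by the
baseline fraction at P ≤ 1. Empty bins are flagged and excluded; the
maximal fold is searched over bins holding ≥ `min_bin` (default 10) SNPs so
one or two SNPs cannot define the maximum, ties breaking to the less
stringent threshold. Overlap significance at a chosen cutoff again reduces
to a hypergeometric draw. The two-study comparison statistic is
fold_A − fold_B at a fixed cutoff, with a null built by independently
swapping each common SNP's A/B significance labels with probability 1/2
(exchangeable when the two label sets are identically distributed);
permutations with an undefined fold count as extreme, which is
conservative.

Reverse direction: f1 is the fraction of all shared pruned SNPs with GWAS
P < p_cut, f2 the same fraction within the eQTL-significant subset
(FDR < fdr_cut), and f2/f1 the relative enrichment, tabulated over both
grids. Inequalities are strict on this grid and non-strict (≤) on the
enrichment curve, matching how the respective cutoffs are stated; f1 = 0
cells are flagged undefined, never divided.

### Mendelian gene-set enrichment

A cis-gene is any gene with ≥ 1 significant cis pair. Given disjoint
epilepsy and other-disorder Mendelian gene lists (a gene appearing in both
curated lists is assigned to the epilepsy list), the 2×2 table against
cis-membership yields the ratio of proportions and a two-sided Fisher exact
P (the standard convention: sum of all table probabilities not exceeding
the observed table's). The two-study comparison uses ratio_A − ratio_B with
a per-gene label-swap null, mirroring the SNP-level comparison.

## The synthetic cohort generator

The generator emulates the statistical structure of a small surgical
brain-tissue eQTL cohort; defaults describe 44 samples.

* **Genotypes.** Per chromosome, SNP allele frequencies are drawn uniformly
  from `maf_range` (default 0.1–0.5, the common-variant range left after
  MAF QC). Haplotypes follow blockwise copy-with-mutation: within a block
  of `ld_block_size` (10) SNPs, each haplotype allele copies the previous
  SNP's allele with probability `ld_decay` (0.9) and otherwise redraws at
  its own frequency, giving adjacent-pair r² ≈ ld_decay² decaying
  geometrically with distance and independence across blocks. Monomorphic
  columns (rare at n = 44) are redrawn independently until polymorphic.
  SNPs are evenly spaced; genes are tiled with fixed span (10 kb) and gap
  (20 kb) so every cis window is non-degenerate and contains SNPs.
  Genotypes are complete by default; `missing_rate` masks entries after
  expression generation, so planted effects stay well-defined.
* **Expression.** A fraction `frac_true_eqtl_genes` (0.2) of genes receive
  an additive effect of a uniformly chosen cis SNP with slope
  ±`effect_size_beta` (1.5) and Gaussian noise `noise_sd` (1.0); all other
  genes are pure noise. The default slope of 1.5 noise-SD per allele
  follows an a-priori power calculation: at n = 44 and MAF 0.1–0.5 the
  per-pair noncentrality is ≈ 1.5·√(2·MAF·(1−MAF)·44) ≈ 4–7, which keeps
  planted pairs detectable after BH correction across a few thousand cis
  tests — the regime in which a small disease-tissue study reports
  significant cis-eQTLs at all. The planted triples are recorded in a
  TruthTable.
* **GWAS.** `n_gwas_true_snps` disease SNPs are drawn without replacement
  with weight `gwas_enrichment_odds` on planted eQTL SNPs; they draw
  P ~ Beta(a, 1) (a = `gwas_beta_a`, default 0.05; one parameter controls
  signal strength), everything else Uniform(0, 1).
* **Validation study.** Each tested discovery pair appears as a significant
  validation pair with probability `validation_replication_rate` (0.15) if
  significant and `validation_background_rate` (0.002) otherwise — the same
  order as published hippocampal replication percentages (~16% vs ~0.1%).
* **Gene sets.** The epilepsy list is drawn with odds
  `geneset_enrichment_odds` (5) on true cis-genes, the other-disorder list
  uniformly from the remainder, disjoint by construction.

One integer seed drives everything; each generator stage derives an
independent child stream from (seed, stage index), so stages are
individually re-runnable and the whole cohort is bit-reproducible.

**What the generator does not emulate:** microarray batch effects and probe
cross-hybridization, imputation uncertainty, case/control expression
differences, realistic genome-wide LD (blocks are local and homogeneous),
population structure, and the scale of a real SNP panel (10³ SNPs vs 10⁶).
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated generative model — not that a real
cohort of this size would reproduce any particular published effect size.

## Validation study designs (frozen)

Three scenario designs drive the statistical acceptance tests and
`scripts/acceptance.py`; their parameters were fixed by the power analyses
below and are exported from `epiqtl.studies`.

* **Null calibration** (200 runs, 199 permutations each): planted cis
  effects exist (so every statistic has non-degenerate counts) but GWAS
  flags, validation inclusion and gene sets are drawn independently of them
  (odds 1, replication rate = background rate 0.5). The design uses 800
  SNPs, 200 genes, a weakly linked panel (ld_decay 0.3, so proxy flags are
  essentially independent across pairs) and high background rates because
  permutation P-values are discrete: only when the overlap statistic has
  standard deviation ≳ 4 counts does the add-one estimator's distribution
  approach Uniform(0, 1) closely enough for a Kolmogorov–Smirnov test at
  n = 200. Expected outcome: all four permutation P-value samples pass KS
  at α = 0.01 and the fold/ratio medians sit at 1.
* **Power** (50 runs): 2000 SNPs, 400 genes (80 with planted effects),
  10:1 odds coupling everywhere (GWAS flags toward planted eQTL SNPs,
  epilepsy genes toward true cis-genes), replication 0.5 vs 0.002, GWAS
  signal Beta(0.01, 1) tested at the 1e-4 cutoff, and a moderately linked
  panel (ld_decay 0.5). The moderate linkage matters: with strong LD the
  causal SNP's neighbours also reach significance, inflating the baseline
  eQTL fraction and compressing the achievable fold enrichment (the fold is
  bounded by roughly 2N/(10K+N) for K causal SNPs among N at 10:1 odds on a
  strongly linked panel). Each of the four permutation tests is required to
  reject at α = 0.05 in ≥ 90% of runs; the design's pilot estimate was
  ≈ 100% for all four.
* **Recovery** (20 runs at generator defaults): sensitivity = fraction of
  planted pairs at FDR < 0.05 (required ≥ 0.8; observed ≈ 0.98) and the
  mean planted-effect estimation error, required within ±2 Monte-Carlo SE
  of zero (OLS on the true model is unbiased; the check is on all planted
  pairs, not the significant subset, to avoid winner's-curse selection).

The two-study comparisons derive "study B" by re-simulating the expression
layer on the same genotype panel at a deterministic seed offset, so A and B
share a SNP universe and GWAS but have independent eQTL structure.

## Numerical and design choices

* Permutation estimator: (b + 1)/(B + 1), NaN permuted statistics counted
  as extreme; bound "< 1/B" reported at b = 0.
* Without-replacement pair/SNP sampling nulls are sampled directly from the
  hypergeometric distribution (exactly equivalent, orders of magnitude
  faster); the equivalence is unit-tested against explicit subset draws.
* All tabular outputs are TSV with fixed column order and `%.10g` float
  formatting; identical config + seed reproduces byte-identical files, and
  the pipeline manifest records the config hash, seed and per-stage row
  counts.
* Tie-breaks are always documented and deterministic: probe selection to
  the smallest probe id, maximal enrichment to the less stringent
  threshold, pruning to the first SNP in position order.
* Degenerate inputs are flagged, not silently dropped: untested pairs carry
  NaN statistics, undefined ratios are NaN/inf with warnings, empty
  enrichment bins are excluded from the maximal-fold search.

## Known limitations

* Only the additive linear model is implemented — no ANOVA genotype
  coding, interactions, trans analysis or mixed models.
* In-sample LD only; with 44 samples r² estimates are noisy, so proxy maps
  on real data of this size would be less reliable than the strict
  threshold suggests.
* The f2/f1 grid and enrichment curve treat SNPs as exchangeable after one
  round of LD pruning; residual correlation below the pruning threshold is
  ignored by the permutation nulls.
* The whole-chromosome r² matrix approach assumes panels of ≤ ~10⁴ SNPs
  per chromosome; genome-scale data would need windowed chunking.
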