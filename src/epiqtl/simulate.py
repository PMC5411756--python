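"""Synthetic cohort generator.

Generates coupled genotype / expression / GWAS / validation-study /
gene-set data with the statistical structure the downstream analyses
assume, under full seed control:

* **Genotypes** — biallelic SNPs in LD blocks on a small number of
  chromosomes.  Within a block each haplotype allele copies the previous
  SNP's allele with probability ``ld_decay`` and otherwise redraws a fresh
  Bernoulli(allele frequency) allele, giving tunable adjacent-pair r²
  (approximately ``ld_decay**2``) that decays geometrically with distance.
  Blocks are independent of each other.
* **Expression** — a chosen fraction of genes receive an additive cis
  effect: expression = beta * dosage(one cis SNP) + N(0, noise_sd²); the
  remaining genes are pure noise.  The planted (SNP, gene, beta) triples
  are recorded in a :class:`TruthTable` for parameter-recovery testing.
* **GWAS summary** — a set of "disease" SNPs is drawn preferentially from
  the planted eQTL SNPs with configurable odds; disease SNPs draw small
  P-values from Beta(a, 1) with a < 1, all other SNPs from Uniform(0, 1).
* **Validation study** — each significant discovery pair replicates with
  probability ``validation_replication_rate``; non-significant pairs
  appear at a small background rate, emulating an independent published
  eQTL study with a controlled replication signal.
* **Mendelian gene sets** — a disease gene list drawn with configurable
  odds in favour of true cis-genes, and a disjoint control list drawn
  uniformly from the remaining genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import ExpressionMatrix, GenotypeMatrix
from .exceptions import ConfigurationError, DataConsistencyError, GenerationError


@dataclass
class TruthTable:
    """Ground truth of the planted structure, for recovery tests.

    ``true_gwas_snps`` is filled by :func:`simulate_gwas` and
    ``true_mendelian_epilepsy_cis_genes`` by :func:`simulate_gene_sets`,
    since only those stages decide the respective memberships.
    """

    true_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    true_gwas_snps: set[str] = field(default_factory=set)
    true_mendelian_epilepsy_cis_genes: set[str] = field(default_factory=set)

    @property
    def true_snps(self) -> set[str]:
        return {snp for snp, _, _ in self.true_pairs}

    @property
    def true_genes(self) -> set[str]:
        return {gene for _, gene, _ in self.true_pairs}


def tile_gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Tile genes along each chromosome with fixed span and gap.

    Gene g on a chromosome occupies
    ``[gap + g*(span+gap) + 1, gap + g*(span+gap) + span]`` (1-based,
    inclusive), so every gene has ``intergene_gap_bp`` of flanking sequence
    and a non-degenerate cis window.  Strand alternates +/- (strand is
    ignored by the cis-window rule but kept for format round-trips).
    """
    rows = []
    gene_idx = 0
    for c, chrom in enumerate(config.chrom_names):
        for g in range(config.genes_per_chrom[c]):
            start = config.intergene_gap_bp + g * (config.gene_span_bp + config.intergene_gap_bp) + 1
            end = start + config.gene_span_bp - 1
            rows.append(
                {
                    "gene_id": f"gene{gene_idx:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": "+" if gene_idx % 2 == 0 else "-",
                }
            )
            gene_idx += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _simulate_chrom_haplotypes(
    rng: np.random.Generator, n_hap: int, n_snps: int, freqs: np.ndarray, block: int, decay: float
) -> np.ndarray:
    """Blockwise copy-with-mutation haplotypes (n_hap x n_snps, 0/1)."""
    H = np.empty((n_hap, n_snps), dtype=np.int8)
    for j in range(n_snps):
        fresh = rng.random(n_hap) < freqs[j]
        if j % block == 0:
            H[:, j] = fresh
        else:
            copy = rng.random(n_hap) < decay
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate dosages and the accompanying variant table.

    SNPs are evenly spaced along each chromosome.  Monomorphic columns
    (possible at small n) are redrawn independently at their allele
    frequency until polymorphic, so every SNP has empirical MAF in
    (0, 0.5]; the redraw breaks that SNP's LD with its block, which is an
    acceptable rarity at the default MAF range.
    """
    rng = config.rng("genotypes")
    n_hap = 2 * config.n_samples
    lo, hi = config.maf_range
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]

    dosage_blocks = []
    var_rows = []
    snp_idx = 0
    for c, chrom in enumerate(config.chrom_names):
        m = config.snps_per_chrom
        freqs = rng.uniform(lo, hi, size=m)
        H = _simulate_chrom_haplotypes(rng, n_hap, m, freqs, config.ld_block_size, config.ld_decay)
        D = (H[0::2] + H[1::2]).astype(float)
        # repair monomorphic columns
        for j in np.flatnonzero(D.min(axis=0) == D.max(axis=0)):
            for _ in range(100):
                h = rng.random((2, config.n_samples)) < freqs[j]
                col = h.sum(axis=0).astype(float)
                if col.min() != col.max():
                    D[:, j] = col
                    break
            else:  # force one heterozygote; vanishingly rare at sane MAF
                D[rng.integers(config.n_samples), j] = 1.0 if D[0, j] != 1.0 else 0.0
        length = config.chrom_length(c)
        positions = np.linspace(1, length, m).round().astype(int)  # sorted by construction
        af = D.mean(axis=0) / 2.0
        maf = np.minimum(af, 1.0 - af)
        for j in range(m):
            var_rows.append(
                {"snp_id": f"rs{snp_idx:05d}", "chrom": chrom, "pos": int(positions[j]), "maf": float(maf[j])}
            )
            snp_idx += 1
        dosage_blocks.append(D)

    dosages = np.concatenate(dosage_blocks, axis=1)
    variants = pd.DataFrame(var_rows, columns=["snp_id", "chrom", "pos", "maf"])
    geno = GenotypeMatrix(sample_ids, variants["snp_id"].tolist(), dosages)
    return geno, variants


def apply_missingness(geno: GenotypeMatrix, config: SimulationConfig) -> GenotypeMatrix:
    """Mask a fraction ``missing_rate`` of dosages as missing (NaN)."""
    if config.missing_rate == 0.0:
        return geno
    rng = config.rng("missingness")
    mask = rng.random(geno.dosages.shape) < config.missing_rate
    dosages = geno.dosages.copy()
    dosages[mask] = np.nan
    return GenotypeMatrix(geno.sample_ids, list(geno.snp_ids), dosages)


def simulate_expression(
    geno: GenotypeMatrix,
    annotation: pd.DataFrame,
    variants: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Plant additive cis effects for a fraction of genes.

    For each "true" gene one cis SNP (within ``cis_window_bp`` of the gene
    body) is chosen uniformly and expression for each of its probes is
    ``sign * effect_size_beta * dosage + N(0, noise_sd²)``, with a random
    effect direction per gene.  All other genes (and all other probes) are
    pure N(0, noise_sd²) noise.
    """
    from .cis import enumerate_cis_pairs  # local import to avoid a cycle

    rng = config.rng("expression")
    pairs = enumerate_cis_pairs(variants, annotation, window=config.cis_window_bp)
    cis_by_gene = pairs.groupby("gene_id")["snp_id"].apply(list).to_dict()

    genes = annotation["gene_id"].tolist()
    n_true = int(round(config.frac_true_eqtl_genes * len(genes)))
    true_genes = sorted(rng.choice(genes, size=n_true, replace=False)) if n_true else []

    truth = TruthTable()
    n, k = config.n_samples, config.probes_per_gene
    probe_ids: list[str] = []
    probe_to_gene: dict[str, str] = {}
    cols: list[np.ndarray] = []
    signal = {}
    for gene in true_genes:
        snps = cis_by_gene.get(gene, [])
        if not snps:
            raise GenerationError(f"gene {gene} selected as true eQTL but has no cis SNP")
        snp = snps[int(rng.integers(len(snps)))]
        beta = float(config.effect_size_beta * rng.choice([-1.0, 1.0]))
        truth.true_pairs.append((snp, gene, beta))
        signal[gene] = beta * np.nan_to_num(geno.column(snp))
    for gene in genes:
        base = signal.get(gene, 0.0)
        for j in range(k):
            probe = f"{gene}_p{j}"
            probe_ids.append(probe)
            probe_to_gene[probe] = gene
            cols.append(base + rng.normal(0.0, config.noise_sd, size=n))
    values = np.column_stack(cols)
    expr = ExpressionMatrix(list(geno.sample_ids), probe_ids, values, probe_to_gene)
    return expr, truth


def simulate_gwas(
    variants: pd.DataFrame, truth: TruthTable, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate per-SNP GWAS association P-values.

    ``n_gwas_true_snps`` disease SNPs are drawn without replacement with
    sampling weight ``gwas_enrichment_odds`` for planted eQTL SNPs and 1
    otherwise; they draw P ~ Beta(gwas_beta_a, 1) (stochastically small for
    a < 1) while every other SNP draws P ~ Uniform(0, 1).  The chosen set is
    recorded in ``truth.true_gwas_snps``.
    """
    rng = config.rng("gwas")
    snp_ids = variants["snp_id"].tolist()
    known = set(snp_ids)
    unknown = truth.true_snps - known
    if unknown:
        raise DataConsistencyError(f"truth references unknown SNP ids: {sorted(unknown)[:5]}")
    if config.n_gwas_true_snps > len(snp_ids):
        raise ConfigurationError("n_gwas_true_snps exceeds the number of SNPs")

    p = rng.uniform(0.0, 1.0, size=len(snp_ids))
    if config.n_gwas_true_snps > 0:
        w = np.ones(len(snp_ids))
        if truth.true_snps:
            is_true = variants["snp_id"].isin(truth.true_snps).to_numpy()
            w[is_true] = config.gwas_enrichment_odds
        flagged_idx = rng.choice(
            len(snp_ids), size=config.n_gwas_true_snps, replace=False, p=w / w.sum()
        )
        p[flagged_idx] = rng.beta(config.gwas_beta_a, 1.0, size=flagged_idx.size)
        truth.true_gwas_snps = {snp_ids[i] for i in flagged_idx}
    else:
        truth.true_gwas_snps = set()

    out = variants[["snp_id", "chrom", "pos"]].copy()
    out["p"] = p
    return out


def simulate_validation_study(
    truth: TruthTable,
    discovery: pd.DataFrame,
    config: SimulationConfig,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Emulate an independent validation eQTL study.

    Each tested discovery pair appears as a *significant* validation pair
    with probability ``validation_replication_rate`` if it is significant
    in the discovery (FDR < ``fdr_threshold``) and with probability
    ``validation_background_rate`` otherwise.  Output columns: ``snp_id``,
    ``gene_id``, ``significant`` (all 1 — only replicating pairs are
    emitted, as published validation eQTL lists carry significant results).
    """
    rng = config.rng("validation")
    tested = discovery[discovery["tested"]]
    sig = tested["fdr"] < fdr_threshold
    prob = np.where(sig, config.validation_replication_rate, config.validation_background_rate)
    take = rng.random(len(tested)) < prob
    out = tested.loc[take, ["snp_id", "gene_id"]].copy()
    out["significant"] = 1
    return out.reset_index(drop=True)


def simulate_gene_sets(
    annotation: pd.DataFrame, truth: TruthTable, config: SimulationConfig
) -> tuple[set[str], set[str]]:
    """Draw disjoint Mendelian "epilepsy" and "other disease" gene sets.

    The epilepsy set is sampled without replacement with weight
    ``geneset_enrichment_odds`` on true cis-genes; the other set uniformly
    from the remaining genes.  The epilepsy true-cis intersection is
    recorded on the truth table.
    """
    rng = config.rng("gene_sets")
    genes = annotation["gene_id"].tolist()
    n_epi = config.n_mendelian_epilepsy_genes
    n_other = config.n_mendelian_other_genes
    if n_epi + n_other > len(genes):
        raise ConfigurationError(
            f"requested {n_epi}+{n_other} Mendelian genes but only {len(genes)} genes exist"
        )
    w = np.ones(len(genes))
    if truth.true_genes:
        w[pd.Index(genes).isin(truth.true_genes)] = config.geneset_enrichment_odds
    epi_idx = rng.choice(len(genes), size=n_epi, replace=False, p=w / w.sum())
    epilepsy = {genes[i] for i in epi_idx}
    rest = [g for g in genes if g not in epilepsy]
    other = set(rng.choice(rest, size=n_other, replace=False))
    truth.true_mendelian_epilepsy_cis_genes = epilepsy & truth.true_genes
    return epilepsy, other


def simulate_cohort(config: SimulationConfig) -> dict:
    """Run all generators in dependency order; returns a dict of artefacts.

    Keys: ``geno``, ``variants``, ``annotation``, ``expr``, ``truth``,
    ``gwas``.  The validation study and gene sets need the discovery eQTL
    results and are generated by the pipeline after mapping.
    """
    geno, variants = simulate_genotypes(config)
    annotation = tile_gene_annotation(config)
    expr, truth = simulate_expression(geno, annotation, variants, config)
    geno = apply_missingness(geno, config)
    gwas = simulate_gwas(variants, truth, config)
    return {
        "geno": geno,
        "variants": variants,
        "annotation": annotation,
        "expr": expr,
        "truth": truth,
        "gwas": gwas,
    }
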