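"""Simulation configuration.

:class:`SimulationConfig` pins down every knob of the synthetic cohort:
sample size, SNP panel geometry and LD structure, gene layout, planted
cis-effect sizes, GWAS signal, validation-study replication behaviour and
Mendelian gene-set composition.  Defaults emulate a small surgical
brain-tissue eQTL cohort: 44 samples, dense local SNP panels in LD blocks,
strong planted cis effects detectable at this sample size (see
docs/methods.md for the power analysis behind the effect-size default).

A single integer seed drives every generator.  Each stage derives an
independent child stream from ``(seed, stage index)`` so that stages can be
re-run in isolation and still reproduce bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import ConfigurationError

# fixed fan-out of the global seed into per-stage streams
_STAGE_KEYS = {
    "genotypes": 1,
    "expression": 2,
    "gwas": 3,
    "validation": 4,
    "gene_sets": 5,
    "missingness": 6,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples: int = 44
    n_chroms: int = 2
    snps_per_chrom: int = 500
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 10
    ld_decay: float = 0.9
    n_genes: int = 100
    gene_span_bp: int = 10_000
    intergene_gap_bp: int = 20_000
    cis_window_bp: int = 20_000
    frac_true_eqtl_genes: float = 0.2
    effect_size_beta: float = 1.5
    noise_sd: float = 1.0
    probes_per_gene: int = 1
    missing_rate: float = 0.0
    # GWAS layer
    n_gwas_true_snps: int = 50
    gwas_enrichment_odds: float = 10.0
    gwas_beta_a: float = 0.05
    # validation-study layer
    validation_replication_rate: float = 0.15
    validation_background_rate: float = 0.002
    # Mendelian gene sets
    n_mendelian_epilepsy_genes: int = 15
    n_mendelian_other_genes: int = 30
    geneset_enrichment_odds: float = 5.0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_chroms": self.n_chroms,
            "snps_per_chrom": self.snps_per_chrom,
            "ld_block_size": self.ld_block_size,
            "n_genes": self.n_genes,
            "gene_span_bp": self.gene_span_bp,
            "intergene_gap_bp": self.intergene_gap_bp,
            "probes_per_gene": self.probes_per_gene,
            "n_mendelian_epilepsy_genes": self.n_mendelian_epilepsy_genes,
            "n_mendelian_other_genes": self.n_mendelian_other_genes,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.cis_window_bp < 0:
            raise ConfigurationError("cis_window_bp must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ConfigurationError("ld_decay must lie in [0, 1)")
        for name in (
            "frac_true_eqtl_genes",
            "missing_rate",
            "validation_replication_rate",
            "validation_background_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("gwas_enrichment_odds", "geneset_enrichment_odds"):
            if getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 < self.gwas_beta_a <= 1.0:
            raise ConfigurationError("gwas_beta_a must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage random stream derived from the global seed."""
        try:
            key = _STAGE_KEYS[stage]
        except KeyError:
            raise ConfigurationError(f"unknown simulation stage {stage!r}") from None
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), key]))

    @property
    def genes_per_chrom(self) -> list[int]:
        """Genes tiled per chromosome (as even a split as possible)."""
        base, extra = divmod(self.n_genes, self.n_chroms)
        return [base + (1 if c < extra else 0) for c in range(self.n_chroms)]

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{c + 1}" for c in range(self.n_chroms)]

    def chrom_length(self, chrom_index: int) -> int:
        """Length covered by the tiled genes plus one trailing gap."""
        n = self.genes_per_chrom[chrom_index]
        return n * (self.gene_span_bp + self.intergene_gap_bp) + self.intergene_gap_bp

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)
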