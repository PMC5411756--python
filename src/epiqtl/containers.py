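"""In-memory containers shared by all pipeline stages.

Tabular objects (variant tables, gene annotation, eQTL results, GWAS
summaries) are plain :class:`pandas.DataFrame` with documented column
schemas; the two matrix-shaped objects get small dataclass wrappers so
sample/column alignment is explicit and checked.

Column schemas
--------------
variant table   : ``snp_id`` (str, unique), ``chrom`` (str), ``pos``
                  (int, 1-based), ``maf`` (float in (0, 0.5]).
gene annotation : ``gene_id`` (str, unique), ``chrom`` (str), ``start``,
                  ``end`` (int, 1-based inclusive, start <= end),
                  ``strand`` ('+'/'-').
eQTL results    : ``snp_id``, ``gene_id``, ``beta``, ``se``, ``t``, ``p``,
                  ``fdr``, ``n_used``, ``tested`` (bool).  Untested pairs
                  (monomorphic dosage or n_used < 4) carry NaN statistics.
GWAS summary    : ``snp_id``, ``chrom``, ``pos``, ``p``.
validation pairs: ``snp_id``, ``gene_id``, ``significant`` (0/1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataConsistencyError

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "maf"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
EQTL_COLUMNS = ["snp_id", "gene_id", "beta", "se", "t", "p", "fdr", "n_used", "tested"]
GWAS_COLUMNS = ["snp_id", "chrom", "pos", "p"]


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix.

    Dosages are floats in {0, 1, 2}; ``NaN`` encodes a missing genotype.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    _snp_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise DataConsistencyError(
                f"dosage matrix is {self.dosages.shape} but there are "
                f"{len(self.sample_ids)} samples and {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != m:
            raise DataConsistencyError("duplicate SNP ids in genotype matrix")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise DataConsistencyError("dosages must lie in {0, 1, 2} or be missing")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector of one SNP across samples."""
        try:
            return self.dosages[:, self._snp_index[snp_id]]
        except KeyError:
            raise DataConsistencyError(f"unknown SNP id {snp_id!r}") from None

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self._snp_index[s] for s in snp_ids]
        return GenotypeMatrix(self.sample_ids, list(snp_ids), self.dosages[:, idx])


@dataclass
class ExpressionMatrix:
    """Samples x probes continuous expression with a probe -> gene map."""

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    probe_to_gene: dict[str, str]
    _probe_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.probe_ids):
            raise DataConsistencyError(
                f"expression matrix is {self.values.shape} but there are "
                f"{len(self.sample_ids)} samples and {len(self.probe_ids)} probes"
            )
        missing = [p for p in self.probe_ids if p not in self.probe_to_gene]
        if missing:
            raise DataConsistencyError(f"probes without a gene mapping: {missing[:5]}")
        self._probe_index = {p: j for j, p in enumerate(self.probe_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def column(self, probe_id: str) -> np.ndarray:
        try:
            return self.values[:, self._probe_index[probe_id]]
        except KeyError:
            raise DataConsistencyError(f"unknown probe id {probe_id!r}") from None

    def gene_to_probe(self) -> dict[str, str]:
        """Invert the probe map; only meaningful after probe selection.

        When several probes still map to one gene the lexicographically
        smallest probe id wins (the same tie-break used by probe selection).
        """
        out: dict[str, str] = {}
        for probe in sorted(self.probe_ids):
            out.setdefault(self.probe_to_gene[probe], probe)
        return out


def check_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Validate the variant-table schema and invariants; returns the input."""
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise DataConsistencyError(f"variant table missing columns {missing}")
    if variants["snp_id"].duplicated().any():
        raise DataConsistencyError("variant table has duplicate snp_ids")
    if (variants["pos"] < 1).any():
        raise DataConsistencyError("variant positions must be >= 1 (1-based)")
    return variants


def check_gene_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise DataConsistencyError(f"gene annotation missing columns {missing}")
    if genes["gene_id"].duplicated().any():
        raise DataConsistencyError("gene annotation has duplicate gene_ids")
    bad = genes["start"] > genes["end"]
    if bad.any():
        raise DataConsistencyError(
            f"gene intervals with start > end: {genes.loc[bad, 'gene_id'].tolist()[:5]}"
        )
    return genes
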