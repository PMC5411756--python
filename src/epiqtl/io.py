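"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as VCF (diploid unphased GT) or as a dosage TSV
(samples x SNPs); gene annotation as BED (0-based half-open on disk,
1-based inclusive in memory); expression, probe maps, GWAS summaries,
validation pairs and eQTL results as TSV; gene lists as one symbol per
line.  All tables are written with a fixed column order and floats
formatted with ``%.10g`` so re-runs are byte-stable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    EQTL_COLUMNS,
    GWAS_COLUMNS,
    ExpressionMatrix,
    GenotypeMatrix,
    check_gene_annotation,
    check_variant_table,
)
from .exceptions import DataConsistencyError

FLOAT_FORMAT = "%.10g"
_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table with the package's stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


_write_tsv = write_tsv


# ---------------------------------------------------------------- genotypes


def write_vcf(geno: GenotypeMatrix, variants: pd.DataFrame, path: str | Path) -> None:
    """Write dosages as a minimal VCF 4.2 with unphased GT calls.

    REF/ALT are placeholder A/B alleles; dosage counts the ALT allele.
    """
    check_variant_table(variants)
    vt = variants.sort_values(["chrom", "pos", "snp_id"], kind="stable")
    order = [geno._snp_index[s] for s in vt["snp_id"]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=epiqtl\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in vt["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.sample_ids) + "\n")
        D = geno.dosages
        for (_, row), j in zip(vt.iterrows(), order):
            calls = "\t".join(
                _GT.get(D[i, j], "./.") if np.isfinite(D[i, j]) else "./."
                for i in range(geno.n_samples)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into dosages (ALT-allele count); multiallelic records skipped."""
    from cyvcf2 import VCF  # deferred: htslib import is slow

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows, cols = [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        gts = rec.genotype.array()  # (n, ploidy+1); -1 = missing
        alleles = gts[:, :2].astype(float)
        dos = np.where((alleles < 0).any(axis=1), np.nan, alleles.clip(min=0).sum(axis=1))
        snp_ids.append(snp_id)
        cols.append(dos)
        rows.append({"snp_id": snp_id, "chrom": rec.CHROM, "pos": rec.POS})
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic VCF records", stacklevel=2)
    if not snp_ids:
        raise DataConsistencyError(f"no usable biallelic records in {path}")
    dosages = np.column_stack(cols)
    af = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame(rows)
    variants["maf"] = np.minimum(af, 1.0 - af)
    return GenotypeMatrix(samples, snp_ids, dosages), variants


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Samples x SNPs dosage table; first column ``sample_id``; NA = missing."""
    df = pd.DataFrame(geno.dosages, columns=geno.snp_ids)
    df.insert(0, "sample_id", geno.sample_ids)
    _write_tsv(df, path)


def write_variants_tsv(variants: pd.DataFrame, path: str | Path) -> None:
    check_variant_table(variants)
    _write_tsv(variants[["snp_id", "chrom", "pos", "maf"]], path)


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    return check_variant_table(df)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise DataConsistencyError(f"{path}: dosage TSV needs a sample_id column")
    samples = df["sample_id"].astype(str).tolist()
    body = df.drop(columns="sample_id")
    return GenotypeMatrix(samples, body.columns.tolist(), body.to_numpy(dtype=float))


# --------------------------------------------------------------- annotation


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene annotation as 6-column BED (0-based half-open)."""
    check_gene_annotation(genes)
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED gene annotation into the 1-based inclusive internal schema."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    genes = pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"],
            "start": bed["start"] + 1,
            "end": bed["end"],
            "strand": bed["strand"],
        }
    )
    return check_gene_annotation(genes)


# --------------------------------------------------------------- expression


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path, map_path: str | Path) -> None:
    """Expression as samples x probes TSV plus a probe -> gene map TSV."""
    df = pd.DataFrame(expr.values, columns=expr.probe_ids)
    df.insert(0, "sample_id", expr.sample_ids)
    _write_tsv(df, path)
    pmap = pd.DataFrame(
        {"probe_id": expr.probe_ids, "gene_id": [expr.probe_to_gene[p] for p in expr.probe_ids]}
    )
    _write_tsv(pmap, map_path)


def read_expression_tsv(path: str | Path, map_path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise DataConsistencyError(f"{path}: expression TSV needs a sample_id column")
    pmap = pd.read_csv(map_path, sep="\t")
    samples = df["sample_id"].astype(str).tolist()
    body = df.drop(columns="sample_id")
    mapping = dict(zip(pmap["probe_id"].astype(str), pmap["gene_id"].astype(str)))
    return ExpressionMatrix(samples, body.columns.tolist(), body.to_numpy(dtype=float), mapping)


# --------------------------------------------------- GWAS / results / lists


def write_gwas_tsv(gwas: pd.DataFrame, path: str | Path) -> None:
    out = gwas.rename(columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "p": "P"})
    _write_tsv(out[["SNP", "CHR", "BP", "P"]], path)


def read_gwas_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"SNP", "CHR", "BP", "P"}
    if not need.issubset(df.columns):
        raise DataConsistencyError(f"{path}: GWAS TSV must have columns {sorted(need)}")
    out = df.rename(columns={"SNP": "snp_id", "CHR": "chrom", "BP": "pos", "P": "p"})
    out["chrom"] = out["chrom"].astype(str)
    return out[GWAS_COLUMNS]


def write_eqtl_tsv(
    eqtl: pd.DataFrame, variants: pd.DataFrame, path: str | Path
) -> None:
    """eQTL results with SNP coordinates merged in."""
    vt = variants.set_index("snp_id")
    out = eqtl.copy()
    out.insert(2, "chrom", vt.loc[out["snp_id"], "chrom"].to_numpy())
    out.insert(3, "pos", vt.loc[out["snp_id"], "pos"].to_numpy())
    _write_tsv(out, path)


def read_eqtl_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise DataConsistencyError(f"{path}: eQTL TSV missing columns {missing}")
    df["tested"] = df["tested"].astype(bool)
    return df


def write_validation_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(pairs[["snp_id", "gene_id", "significant"]], path)


def read_validation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"snp_id", "gene_id", "significant"}
    if not need.issubset(df.columns):
        raise DataConsistencyError(f"{path}: validation TSV must have columns {sorted(need)}")
    return df


def write_gene_list(genes: set[str] | list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
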