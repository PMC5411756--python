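"""GWAS-eQTL enrichment statistics.

Forward direction — are GWAS signals enriched for eQTLs?  Over the
LD-pruned SNPs shared between the GWAS and the eQTL study, the fraction of
SNPs that are significant eQTLs is computed at a descending ladder of GWAS
P-value cutoffs and expressed as a fold over the baseline fraction at
P <= 1; significance of the overlap at a chosen cutoff comes from drawing
random SNP sets of the same size.

Reverse direction — are significant eQTL SNPs enriched for GWAS signal?
f1 = fraction of all shared pruned SNPs with GWAS P below a cutoff,
f2 = the same fraction within the eQTL-significant subset; f2/f1 is the
relative enrichment, tabulated over a grid of GWAS and FDR cutoffs.

Inequality conventions: ``gwas_p <= t`` on the enrichment curve (the
baseline is P <= 1) and strict ``gwas_p < p_cut`` / ``fdr < fdr_cut`` in
the f1/f2 grid.  Each SNP carries its minimum FDR across all its cis genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .exceptions import AnalysisError, DataConsistencyError
from .ld import ld_prune
from .permutation import PermutationResult, count_as_extreme

DEFAULT_GWAS_THRESHOLDS = (1.0, 0.5, 0.1, 0.05, 0.01, 1e-3, 1e-4, 1e-5, 1e-6)


def shared_pruned_snps(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
    prune: bool = True,
) -> pd.DataFrame:
    """Shared GWAS/eQTL SNPs, LD-pruned, annotated with (gwas_p, min_eqtl_fdr).

    The eQTL side contributes every SNP with at least one tested cis pair;
    a SNP tested against several genes keeps its lowest FDR.
    """
    tested = eqtl[eqtl["tested"]]
    min_fdr = tested.groupby("snp_id")["fdr"].min()
    shared = sorted(set(gwas["snp_id"]) & set(min_fdr.index))
    if not shared:
        raise AnalysisError("no SNPs shared between the GWAS and the eQTL study")
    if prune:
        shared = ld_prune(shared, geno, variants, r2_threshold=r2_threshold, window_bp=window_bp)
    gw = gwas.set_index("snp_id")
    out = pd.DataFrame(
        {
            "snp_id": shared,
            "gwas_p": gw.loc[shared, "p"].to_numpy(dtype=float),
            "min_eqtl_fdr": min_fdr.loc[shared].to_numpy(dtype=float),
        }
    )
    return out


@dataclass
class EnrichmentCurve:
    """Enrichment of significant eQTLs along descending GWAS P cutoffs."""

    table: pd.DataFrame  # threshold, n_gwas_snps, n_eqtl, fraction, fold, defined
    eqtl_fdr_cut: float

    @property
    def baseline_fraction(self) -> float:
        return float(self.table.loc[self.table["threshold"] == 1.0, "fraction"].iloc[0])


def enrichment_curve(
    snps: pd.DataFrame,
    eqtl_fdr_cut: float = 0.05,
    thresholds: tuple[float, ...] = DEFAULT_GWAS_THRESHOLDS,
) -> EnrichmentCurve:
    """Fraction (and fold over baseline) of eQTL-significant SNPs at each cutoff."""
    thresholds = tuple(sorted(set(thresholds), reverse=True))
    if 1.0 not in thresholds:
        raise ValueError("thresholds must include the baseline 1.0")
    p = snps["gwas_p"].to_numpy()
    sig = snps["min_eqtl_fdr"].to_numpy() < eqtl_fdr_cut
    rows = []
    for t in thresholds:
        at = p <= t
        n = int(at.sum())
        k = int((at & sig).sum())
        frac = k / n if n else np.nan
        rows.append({"threshold": t, "n_gwas_snps": n, "n_eqtl": k, "fraction": frac, "defined": n > 0})
    tbl = pd.DataFrame(rows)
    base = tbl.loc[tbl["threshold"] == 1.0, "fraction"].iloc[0]
    if not base > 0:
        raise AnalysisError("baseline eQTL fraction is zero; no significant eQTLs among shared SNPs")
    tbl["fold"] = tbl["fraction"] / base
    return EnrichmentCurve(table=tbl, eqtl_fdr_cut=eqtl_fdr_cut)


def max_enrichment(curve: EnrichmentCurve, min_bin: int = 10) -> tuple[float, float]:
    """(threshold, fold) of the maximal-fold bin among bins with >= min_bin SNPs.

    Ties break toward the less stringent (larger) threshold.
    """
    tbl = curve.table
    ok = tbl["defined"] & (tbl["n_gwas_snps"] >= min_bin)
    if not ok.any():
        raise AnalysisError(f"no threshold bin holds >= {min_bin} SNPs")
    sub = tbl[ok].sort_values("threshold", ascending=False, kind="stable")
    best = sub.loc[sub["fold"].idxmax()]  # idxmax returns the first max -> least stringent
    return float(best["threshold"]), float(best["fold"])


def permute_enrichment(
    snps: pd.DataFrame,
    eqtl_fdr_cut: float = 0.05,
    threshold: float = 1e-3,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Significance of the eQTL count among GWAS-passing SNPs.

    The null draws, per permutation, a random SNP set of the same size as
    the GWAS-passing set from the shared pruned list and counts significant
    eQTLs among it — a hypergeometric draw, sampled directly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    p = snps["gwas_p"].to_numpy()
    sig = snps["min_eqtl_fdr"].to_numpy() < eqtl_fdr_cut
    at = p <= threshold
    k = int(at.sum())
    if k == 0:
        raise AnalysisError(f"no SNPs pass the GWAS threshold {threshold}")
    observed = int((at & sig).sum())
    rng = np.random.default_rng(seed)
    n_sig = int(sig.sum())
    perm_counts = rng.hypergeometric(n_sig, len(snps) - n_sig, k, size=n_perm)
    b = count_as_extreme(perm_counts, observed)
    return PermutationResult(observed=float(observed), b=b, n_perm=n_perm)


def _fold_at(p: np.ndarray, sig: np.ndarray, threshold: float) -> float:
    """Fold enrichment of eQTL-significant SNPs at one GWAS cutoff."""
    at = p <= threshold
    n_at = at.sum()
    n_sig = sig.sum()
    if n_at == 0 or n_sig == 0:
        return np.nan
    return ((at & sig).sum() / n_at) / (n_sig / p.size)


def compare_enrichment(
    snps_a: pd.DataFrame,
    snps_b: pd.DataFrame,
    threshold: float,
    eqtl_fdr_cut: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Is study A's enrichment fold higher than study B's at one cutoff?

    Both studies are reduced to their common SNP universe (shared GWAS P
    per SNP).  Observed statistic: fold_A - fold_B.  Null: each SNP's A/B
    eQTL-significance labels are independently swapped with probability
    1/2, which is exchangeable when the two studies' labels are identically
    distributed.  Permutations with an undefined fold count as extreme
    (conservative).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = snps_a.set_index("snp_id")
    b = snps_b.set_index("snp_id")
    common = a.index.intersection(b.index)
    if common.empty:
        raise AnalysisError("the two studies share no SNPs")
    pa = a.loc[common, "gwas_p"].to_numpy(dtype=float)
    pb = b.loc[common, "gwas_p"].to_numpy(dtype=float)
    if not np.allclose(pa, pb):
        raise DataConsistencyError("the two studies carry different GWAS P-values for shared SNPs")
    sig_a = a.loc[common, "min_eqtl_fdr"].to_numpy(dtype=float) < eqtl_fdr_cut
    sig_b = b.loc[common, "min_eqtl_fdr"].to_numpy(dtype=float) < eqtl_fdr_cut

    observed = _fold_at(pa, sig_a, threshold) - _fold_at(pa, sig_b, threshold)
    if np.isnan(observed):
        raise AnalysisError("observed fold undefined in one of the studies")

    rng = np.random.default_rng(seed)
    n = common.size
    stats = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.random(n) < 0.5
        a_lab = np.where(swap, sig_b, sig_a)
        b_lab = np.where(swap, sig_a, sig_b)
        stats[i] = _fold_at(pa, a_lab, threshold) - _fold_at(pa, b_lab, threshold)
    b_count = count_as_extreme(stats, observed)
    return PermutationResult(observed=float(observed), b=b_count, n_perm=n_perm)


@dataclass
class ReverseEnrichmentGrid:
    """f2/f1 relative enrichment over (GWAS P cutoff, eQTL FDR cutoff) cells."""

    table: pd.DataFrame  # p_cut, fdr_cut, f1, f2, relative_enrichment, defined


def reverse_enrichment_grid(
    snps: pd.DataFrame,
    gwas_p_grid: tuple[float, ...],
    eqtl_fdr_grid: tuple[float, ...],
) -> ReverseEnrichmentGrid:
    """Tabulate f1, f2 and f2/f1 over the cutoff grid (strict < on both axes)."""
    if not len(gwas_p_grid) or not len(eqtl_fdr_grid):
        raise ValueError("both cutoff grids must be non-empty")
    p = snps["gwas_p"].to_numpy()
    fdr = snps["min_eqtl_fdr"].to_numpy()
    n = p.size
    rows = []
    for p_cut in gwas_p_grid:
        f1 = (p < p_cut).sum() / n
        for fdr_cut in eqtl_fdr_grid:
            in_sub = fdr < fdr_cut
            m = int(in_sub.sum())
            f2 = (in_sub & (p < p_cut)).sum() / m if m else np.nan
            defined = f1 > 0 and m > 0
            rows.append(
                {
                    "p_cut": p_cut,
                    "fdr_cut": fdr_cut,
                    "f1": f1,
                    "f2": f2,
                    "relative_enrichment": f2 / f1 if defined else np.nan,
                    "defined": defined,
                }
            )
    return ReverseEnrichmentGrid(table=pd.DataFrame(rows))
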