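"""Linkage-disequilibrium tools: pairwise r², greedy pruning, proxy lookup.

LD is measured as the squared Pearson correlation of additive dosages over
pairwise-complete samples (composite, phase-free r²), computed from the
supplied genotype matrix — no external reference panel.  Both the pruning
and the proxy rules use a strict inequality (r² > threshold); a threshold
of 1.0 can never be exceeded, so it prunes nothing and yields an empty
proxy map.

Pairwise r² over many SNPs is computed blockwise per chromosome with
masked matrix algebra (missing genotypes zero-filled and all moments
accumulated over the joint-presence mask), so pruning and proxy-map
construction stay O(matrix product) rather than O(pairs) Python loops.
This holds whole-chromosome r² matrices in memory, which is fine at the
panel sizes this package targets (10²-10⁴ SNPs per chromosome).
"""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, check_variant_table
from .exceptions import UndefinedLdError

MIN_COMPLETE_PAIRS = 4


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete samples; requires >= 4 complete pairs and both
    vectors polymorphic on the complete subset.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = np.isfinite(g1) & np.isfinite(g2)
    if mask.sum() < MIN_COMPLETE_PAIRS:
        raise UndefinedLdError(f"only {int(mask.sum())} pairwise-complete samples (need >= 4)")
    a, b = g1[mask], g2[mask]
    if a.min() == a.max() or b.min() == b.max():
        raise UndefinedLdError("monomorphic dosage vector; LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def pairwise_r2(D: np.ndarray) -> np.ndarray:
    """All-pairs r² of a samples x SNPs dosage block (NaN = missing).

    Entry (a, b) is the squared Pearson correlation over samples where both
    SNPs are observed; NaN where LD is undefined (fewer than 4 complete
    pairs or a monomorphic SNP on the joint subset).  The diagonal is 1 for
    polymorphic SNPs.
    """
    D = np.asarray(D, dtype=float)
    W = np.isfinite(D).astype(float)
    X = np.where(np.isfinite(D), D, 0.0)
    n = W.T @ W
    sx = X.T @ W  # sum of x over the joint mask
    sxx = (X * X).T @ W
    sxy = X.T @ X
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        r2 = cov**2 / (varx * varx.T)
        r2 = np.where((n >= MIN_COMPLETE_PAIRS) & (varx > 0) & (varx.T > 0), r2, np.nan)
    return np.minimum(r2, 1.0)


def _by_chrom(
    snps: list[str], geno: GenotypeMatrix, variants: pd.DataFrame
):
    """Yield (chrom, snp ids sorted by position, positions, dosage block)."""
    vt = variants.set_index("snp_id")
    missing = [s for s in snps if s not in vt.index]
    if missing:
        raise KeyError(f"SNPs absent from variant table: {missing[:5]}")
    sub = vt.loc[snps].reset_index()
    for chrom, grp in sub.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos", "snp_id"], kind="stable")
        ids = grp["snp_id"].tolist()
        pos = grp["pos"].to_numpy(dtype=int)
        block = np.column_stack([geno.column(s) for s in ids])
        yield chrom, ids, pos, block


def ld_prune(
    snps: list[str],
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
) -> list[str]:
    """Greedy positional LD pruning.

    Scans SNPs in (chrom, pos) order; a SNP is dropped iff its r² with an
    already-retained SNP on the same chromosome within ``window_bp``
    exceeds ``r2_threshold`` (strict).  SNPs whose LD is undefined
    (monomorphic) are retained untested with a warning.  Output preserves
    the scan order.
    """
    check_variant_table(variants)
    retained: list[str] = []
    n_untested = 0
    for _chrom, ids, pos, block in _by_chrom(snps, geno, variants):
        r2 = pairwise_r2(block)
        kept: list[int] = []
        for j in range(len(ids)):
            drop = False
            for k in reversed(kept):
                if pos[j] - pos[k] > window_bp:
                    break
                v = r2[j, k]
                if np.isnan(v):
                    n_untested += 1
                elif v > r2_threshold:
                    drop = True
                    break
            if not drop:
                kept.append(j)
                retained.append(ids[j])
    if n_untested:
        warnings.warn(
            f"{n_untested} SNP comparisons had undefined LD (monomorphic); those SNPs "
            "were retained untested",
            stacklevel=2,
        )
    return retained


def build_proxy_map(
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
) -> dict[str, set[tuple[str, float]]]:
    """All within-window SNP pairs with r² strictly above the threshold.

    Returns a symmetric map snp_id -> {(proxy_snp_id, r²), ...}; a SNP is
    never its own proxy.  Monomorphic SNPs simply acquire no proxies.
    """
    check_variant_table(variants)
    proxies: dict[str, set[tuple[str, float]]] = defaultdict(set)
    for _chrom, ids, pos, block in _by_chrom(list(variants["snp_id"]), geno, variants):
        r2 = pairwise_r2(block)
        in_window = np.abs(pos[:, None] - pos[None, :]) <= window_bp
        with np.errstate(invalid="ignore"):
            hit = np.triu((r2 > r2_threshold) & in_window, k=1)
        for a_idx, b_idx in zip(*np.nonzero(hit)):
            a, b, v = ids[a_idx], ids[b_idx], float(r2[a_idx, b_idx])
            proxies[a].add((b, v))
            proxies[b].add((a, v))
    return dict(proxies)


def proxy_map_to_frame(proxies: dict[str, set[tuple[str, float]]]) -> pd.DataFrame:
    """Flatten a proxy map to a (snp_a, snp_b, r2) table, one row per pair."""
    rows = []
    for a, partners in proxies.items():
        for b, r2 in partners:
            if a < b:
                rows.append({"snp_a": a, "snp_b": b, "r2": r2})
    df = pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])
    return df.sort_values(["snp_a", "snp_b"], kind="stable").reset_index(drop=True)


def frame_to_proxy_map(df: pd.DataFrame) -> dict[str, set[tuple[str, float]]]:
    """Inverse of :func:`proxy_map_to_frame` (restores symmetry)."""
    proxies: dict[str, set[tuple[str, float]]] = defaultdict(set)
    for a, b, r2 in zip(df["snp_a"], df["snp_b"], df["r2"]):
        proxies[a].add((b, float(r2)))
        proxies[b].add((a, float(r2)))
    return dict(proxies)
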