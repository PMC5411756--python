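"""Per-SNP quality control.

Filters SNPs on minor allele frequency, genotype call rate and
Hardy-Weinberg equilibrium (exact test).  Defaults: MAF >= 0.05,
call rate >= 0.95, HWE exact P >= 1e-6.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


@lru_cache(maxsize=100_000)
def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg P-value from genotype counts.

    Sums the probabilities of all heterozygote counts (with fixed allele
    counts) no more probable than the observed one, using the standard
    conditional distribution of heterozygotes given allele counts.
    """
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n == 0:
        return 1.0
    # heterozygote count has the parity of the minor-allele count
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    # log-probability up to a constant: P(h) ∝ n_minor! n_major! n! 2^h / ((nm-h)/2)! h! ((nM-h)/2)!
    from scipy.special import gammaln

    n_major = 2 * n - n_minor
    logp = (
        hets * np.log(2.0)
        - gammaln((n_minor - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_major - hets) / 2 + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


def snp_qc(
    geno: GenotypeMatrix,
    variants: pd.DataFrame,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs failing MAF, call-rate or HWE thresholds.

    Returns the filtered genotype matrix and variant table (MAF column
    recomputed from the observed genotypes).
    """
    D = geno.dosages
    n = geno.n_samples
    call_rate = np.isfinite(D).mean(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)

    keep = (call_rate >= call_rate_min) & (maf >= maf_min)
    for j in np.flatnonzero(keep):
        col = D[:, j]
        col = col[np.isfinite(col)]
        n_minor_hom = int((col == 2).sum()) if af[j] <= 0.5 else int((col == 0).sum())
        n_major_hom = int((col == 0).sum()) if af[j] <= 0.5 else int((col == 2).sum())
        n_het = int((col == 1).sum())
        if hwe_exact_p(n_het, n_minor_hom, n_major_hom) < hwe_p_min:
            keep[j] = False

    kept_ids = [s for s, k in zip(geno.snp_ids, keep) if k]
    out_geno = GenotypeMatrix(geno.sample_ids, kept_ids, D[:, keep])
    out_var = variants[variants["snp_id"].isin(kept_ids)].copy()
    out_var["maf"] = out_var["snp_id"].map(dict(zip(geno.snp_ids, maf)))
    return out_geno, out_var.reset_index(drop=True)
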