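"""cis-eQTL mapping.

Enumerates SNP-gene pairs within a cis window (default 20 kb of the gene
body, boundary inclusive), selects one probe per gene (highest sample
variance), optionally residualizes expression on covariates, fits per-pair
ordinary least squares of expression on additive dosage, and controls the
false discovery rate with the Benjamini-Hochberg procedure applied jointly
across all tested cis pairs.

Conventions
-----------
* cis distance is 0 for a SNP inside the gene body, otherwise the base-pair
  gap to the nearest gene edge; a pair is cis iff distance <= window.
* Missing dosages are handled per pair by complete-case analysis; pairs
  with fewer than 4 usable samples or a monomorphic dosage are flagged
  untested and excluded from the FDR.
* Two-sided t-test P-values are floored at 1e-300 to avoid underflow.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    EQTL_COLUMNS,
    ExpressionMatrix,
    GenotypeMatrix,
    check_gene_annotation,
    check_variant_table,
)
from .exceptions import AnalysisError, DataConsistencyError

P_FLOOR = 1e-300
MIN_SAMPLES_PER_PAIR = 4


def enumerate_cis_pairs(
    variants: pd.DataFrame, genes: pd.DataFrame, window: int = 20_000
) -> pd.DataFrame:
    """List all SNP-gene pairs with cis distance <= ``window``.

    Coordinates are 1-based inclusive on both inputs.  SNPs on chromosomes
    absent from the gene annotation are skipped with a warning.  Returns a
    DataFrame with columns ``snp_id``, ``gene_id``, ``distance``.
    """
    if window < 0:
        raise ValueError(f"cis window must be >= 0, got {window}")
    check_variant_table(variants)
    check_gene_annotation(genes)

    gene_chroms = set(genes["chrom"])
    orphan = sorted(set(variants["chrom"]) - gene_chroms)
    if orphan:
        warnings.warn(f"SNPs on chromosomes without genes skipped: {orphan}", stacklevel=2)

    out = []
    for chrom, gsub in genes.groupby("chrom", sort=False):
        vsub = variants[variants["chrom"] == chrom]
        if vsub.empty:
            continue
        pos = vsub["pos"].to_numpy()
        snp_ids = vsub["snp_id"].to_numpy()
        for gene_id, start, end in zip(gsub["gene_id"], gsub["start"], gsub["end"]):
            dist = np.maximum(0, np.maximum(start - pos, pos - end))
            keep = dist <= window
            if keep.any():
                out.append(
                    pd.DataFrame(
                        {"snp_id": snp_ids[keep], "gene_id": gene_id, "distance": dist[keep]}
                    )
                )
    if not out:
        return pd.DataFrame(columns=["snp_id", "gene_id", "distance"])
    return pd.concat(out, ignore_index=True)


def select_probes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Keep, per gene, the probe with the highest sample variance.

    Exact variance ties are broken toward the lexicographically smallest
    probe id.  Genes with a single probe pass through unchanged.
    """
    var = np.var(expr.values, axis=0, ddof=1)
    tbl = pd.DataFrame(
        {
            "probe_id": expr.probe_ids,
            "gene_id": [expr.probe_to_gene[p] for p in expr.probe_ids],
            "variance": var,
        }
    )
    # sort: variance descending, probe id ascending -> first row per gene wins
    tbl = tbl.sort_values(["variance", "probe_id"], ascending=[False, True], kind="stable")
    winner_set = set(tbl.drop_duplicates("gene_id")["probe_id"])
    keep = [p for p in expr.probe_ids if p in winner_set]  # original column order
    index_map = {p: j for j, p in enumerate(expr.probe_ids)}
    idx = [index_map[p] for p in keep]
    return ExpressionMatrix(
        expr.sample_ids,
        list(keep),
        expr.values[:, idx],
        {p: expr.probe_to_gene[p] for p in keep},
    )


def residualize_covariates(expr: ExpressionMatrix, covariates: pd.DataFrame) -> ExpressionMatrix:
    """Replace each probe by its OLS residuals on covariates + intercept.

    ``covariates`` is a samples x k table aligned to ``expr.sample_ids``
    (by index when the index holds sample ids, else by row order).  With
    zero covariates this mean-centres each probe.  Rank-deficient
    covariates raise an error naming the collinear columns.
    """
    n = expr.n_samples
    if covariates.shape[0] != n:
        raise DataConsistencyError(
            f"covariates have {covariates.shape[0]} rows for {n} samples"
        )
    if set(covariates.index) == set(expr.sample_ids):
        covariates = covariates.loc[expr.sample_ids]
    k = covariates.shape[1]
    if k >= n - 2:
        raise DataConsistencyError(f"{k} covariates for {n} samples leaves too few df")

    X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    # collinearity check with column names via greedy rank growth
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        kept = np.ones((n, 1))
        for j, name in enumerate(covariates.columns):
            cand = np.column_stack([kept, X[:, j + 1]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(str(name))
            else:
                kept = cand
        raise DataConsistencyError(f"collinear covariate columns: {bad}")

    coef, *_ = np.linalg.lstsq(X, expr.values, rcond=None)
    resid = expr.values - X @ coef
    return ExpressionMatrix(expr.sample_ids, list(expr.probe_ids), resid, dict(expr.probe_to_gene))


def fit_cis_model(
    geno: GenotypeMatrix, expr: ExpressionMatrix, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Per-pair OLS of expression on additive dosage + intercept.

    Returns the eQTL result table (one row per input pair, input order
    preserved) with slope, standard error, t, two-sided P and BH FDR across
    all tested pairs.  Untested pairs (monomorphic dosage on the complete
    cases, or n_used < 4) carry NaN statistics and ``tested = False``.
    """
    if geno.sample_ids != expr.sample_ids:
        raise DataConsistencyError("genotype and expression samples are not aligned")
    if pairs.empty:
        raise AnalysisError("no cis pairs to test")

    gene_probe = expr.gene_to_probe()
    missing_genes = sorted(set(pairs["gene_id"]) - set(gene_probe))
    if missing_genes:
        raise DataConsistencyError(f"pairs reference genes without probes: {missing_genes[:5]}")

    G = np.column_stack([geno.column(s) for s in pairs["snp_id"]])
    Y = np.column_stack([expr.column(gene_probe[g]) for g in pairs["gene_id"]])

    W = np.isfinite(G) & np.isfinite(Y)
    Gz = np.where(W, G, 0.0)
    Yz = np.where(W, Y, 0.0)
    n_used = W.sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        gm = Gz.sum(axis=0) / n_used
        ym = Yz.sum(axis=0) / n_used
        Gc = np.where(W, Gz - gm, 0.0)
        Yc = np.where(W, Yz - ym, 0.0)
        sxx = (Gc * Gc).sum(axis=0)
        sxy = (Gc * Yc).sum(axis=0)
        syy = (Yc * Yc).sum(axis=0)

        tested = (n_used >= MIN_SAMPLES_PER_PAIR) & (sxx > 0)
        if not tested.any():
            raise AnalysisError("no testable cis pairs (all monomorphic or too few samples)")

        beta = np.where(tested, sxy / np.where(sxx > 0, sxx, np.nan), np.nan)
        rss = np.maximum(syy - beta * sxy, 0.0)
        df = n_used - 2
        sigma2 = rss / np.where(df > 0, df, np.nan)
        se = np.sqrt(sigma2 / np.where(sxx > 0, sxx, np.nan))
        t = np.where(se > 0, beta / se, np.where(np.isfinite(beta), np.inf * np.sign(beta), np.nan))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(df, 1))
        p = np.maximum(p, P_FLOOR)

    out = pd.DataFrame(
        {
            "snp_id": pairs["snp_id"].to_numpy(),
            "gene_id": pairs["gene_id"].to_numpy(),
            "beta": np.where(tested, beta, np.nan),
            "se": np.where(tested, se, np.nan),
            "t": np.where(tested, t, np.nan),
            "p": np.where(tested, p, np.nan),
            "fdr": np.nan,
            "n_used": n_used,
            "tested": tested,
        },
        columns=EQTL_COLUMNS,
    )
    out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values: q_i = min_{p_j >= p_i} p_j * m / rank_j.

    Order is preserved relative to the input; values are clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def stratification_check(
    geno: GenotypeMatrix, expr: ExpressionMatrix, n_pcs: int = 10
) -> pd.DataFrame:
    """Correlate top genotype principal components with probe expression.

    A lightweight population-stratification screen: dosages are mean-imputed
    and standardized, PCs taken from the sample-covariance SVD, and each of
    the top ``n_pcs`` PCs Pearson-correlated with every probe.  Returns one
    row per PC with ``pc``, ``min_p`` (smallest correlation P across
    probes), ``frac_p_lt_05`` and ``n_probes``; under no stratification the
    fraction below 0.05 stays near 0.05.
    """
    n = geno.n_samples
    if n_pcs >= n:
        raise ValueError(f"n_pcs must be < n_samples ({n}), got {n_pcs}")
    if geno.sample_ids != expr.sample_ids:
        raise DataConsistencyError("genotype and expression samples are not aligned")

    D = geno.dosages.copy()
    col_mean = np.nanmean(D, axis=0)
    inds = np.where(np.isnan(D))
    D[inds] = np.take(col_mean, inds[1])
    sd = D.std(axis=0, ddof=1)
    keep = sd > 0
    Z = (D[:, keep] - D[:, keep].mean(axis=0)) / sd[keep]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :n_pcs] * S[:n_pcs]

    E = expr.values
    Ec = (E - E.mean(axis=0)) / E.std(axis=0, ddof=1)
    Pc = (pcs - pcs.mean(axis=0)) / pcs.std(axis=0, ddof=1)
    r = (Pc.T @ Ec) / (n - 1)  # n_pcs x n_probes
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pvals = np.where(np.isnan(pvals), 0.0, pvals)  # |r| == 1 -> p = 0

    return pd.DataFrame(
        {
            "pc": np.arange(1, n_pcs + 1),
            "min_p": pvals.min(axis=1),
            "frac_p_lt_05": (pvals < 0.05).mean(axis=1),
            "n_probes": expr.n_probes,
        }
    )
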