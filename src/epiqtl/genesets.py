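"""Mendelian-disease gene-set enrichment of cis-genes.

A cis-gene is a gene with at least one significant (FDR < 0.05) cis-eQTL.
The question: is a Mendelian epilepsy gene more likely to be a cis-gene
than a Mendelian gene for another disorder?  Answered with the ratio of
the two proportions and a two-sided Fisher exact test on the 2x2 table
[[epilepsy ∩ cis, epilepsy \\ cis], [other ∩ cis, other \\ cis]].
A permutation test (per-gene swap of the two studies' cis labels) compares
the enrichment ratio between two eQTL studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError
from .permutation import PermutationResult, count_as_extreme


def classify_cis_genes(eqtl: pd.DataFrame, fdr_cut: float = 0.05) -> set[str]:
    """Genes with >= 1 tested pair at FDR < ``fdr_cut``."""
    tested = eqtl[eqtl["tested"]]
    hit = tested[tested["fdr"] < fdr_cut]
    return set(hit["gene_id"])


@dataclass
class GeneSetEnrichmentResult:
    table2x2: tuple[tuple[int, int], tuple[int, int]]
    prop_epilepsy: float
    prop_other: float
    fisher_p: float
    comparative_perm: PermutationResult | None = None

    @property
    def ratio(self) -> float:
        """prop_epilepsy / prop_other; inf when no control gene is a cis-gene."""
        if self.prop_other == 0:
            return math.inf if self.prop_epilepsy > 0 else math.nan
        return self.prop_epilepsy / self.prop_other


def mendelian_enrichment(
    cis_genes: set[str], epilepsy_genes: set[str], other_genes: set[str]
) -> GeneSetEnrichmentResult:
    """Ratio of cis-gene proportions and two-sided Fisher exact P.

    ``epilepsy_genes`` and ``other_genes`` must be disjoint and non-empty.
    """
    if epilepsy_genes & other_genes:
        raise ValueError(
            f"gene sets overlap: {sorted(epilepsy_genes & other_genes)[:5]}"
        )
    if not epilepsy_genes or not other_genes:
        raise ValueError("both Mendelian gene sets must be non-empty")
    a = len(epilepsy_genes & cis_genes)
    b = len(epilepsy_genes) - a
    c = len(other_genes & cis_genes)
    d = len(other_genes) - c
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return GeneSetEnrichmentResult(
        table2x2=((a, b), (c, d)),
        prop_epilepsy=a / len(epilepsy_genes),
        prop_other=c / len(other_genes),
        fisher_p=float(fisher_p),
    )


def _ratio(cis: np.ndarray, epi: np.ndarray, other: np.ndarray) -> float:
    pe = (cis & epi).sum() / epi.sum()
    po = (cis & other).sum() / other.sum()
    return pe / po if po > 0 else np.nan


def compare_gene_enrichment(
    cis_a: set[str],
    cis_b: set[str],
    epilepsy_genes: set[str],
    other_genes: set[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Is study A's Mendelian enrichment ratio higher than study B's?

    Observed statistic: ratio_A - ratio_B over the union of the two
    Mendelian lists.  Null: each gene's A/B cis-membership labels swapped
    independently with probability 1/2.  Permutations with an undefined
    ratio count as extreme (conservative).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res_a = mendelian_enrichment(cis_a, epilepsy_genes, other_genes)
    res_b = mendelian_enrichment(cis_b, epilepsy_genes, other_genes)
    if not (math.isfinite(res_a.ratio) and math.isfinite(res_b.ratio)):
        raise AnalysisError(
            f"enrichment ratio undefined or infinite (A={res_a.ratio}, B={res_b.ratio}); "
            "the comparative permutation needs finite ratios in both studies"
        )
    observed = res_a.ratio - res_b.ratio

    genes = sorted(epilepsy_genes | other_genes)
    epi = np.array([g in epilepsy_genes for g in genes])
    other = ~epi
    in_a = np.array([g in cis_a for g in genes])
    in_b = np.array([g in cis_b for g in genes])

    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.random(len(genes)) < 0.5
        a_lab = np.where(swap, in_b, in_a)
        b_lab = np.where(swap, in_a, in_b)
        perm_stats[i] = _ratio(a_lab, epi, other) - _ratio(b_lab, epi, other)
    b_count = count_as_extreme(perm_stats, observed)
    return PermutationResult(observed=float(observed), b=b_count, n_perm=n_perm)
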