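"""Cross-study replication of SNP-gene pairs.

A discovery pair replicates if the same (SNP, gene) pair is a significant
eQTL in the validation study, or if a proxy of the SNP (r² > 0.8 by
default, supplied as an LD proxy map) is a significant validation eQTL for
the *same* gene.  Replication is summarized as the percentage of
significant (FDR < 0.05) discovery pairs that replicate, the same
percentage for non-significant pairs, and their ratio; significance of the
observed overlap is assessed by drawing random pair sets of the same size
from the discovery pair universe.

Gene identifiers must already be harmonized across studies (exact string
equality); id conversion is the caller's job.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .permutation import PermutationResult, count_as_extreme


@dataclass
class ReplicationResult:
    n_sig_pairs: int
    n_sig_replicated: int
    n_nonsig_pairs: int
    n_nonsig_replicated: int
    perm: PermutationResult | None = None

    @property
    def pct_sig(self) -> float:
        """Percent of significant pairs replicated (NaN if no significant pairs)."""
        return 100.0 * self.n_sig_replicated / self.n_sig_pairs if self.n_sig_pairs else math.nan

    @property
    def pct_nonsig(self) -> float:
        return (
            100.0 * self.n_nonsig_replicated / self.n_nonsig_pairs
            if self.n_nonsig_pairs
            else math.nan
        )

    @property
    def relative_ratio(self) -> float:
        """pct_sig / pct_nonsig; inf when nothing non-significant replicates."""
        if self.n_sig_pairs == 0 or self.n_nonsig_pairs == 0:
            return math.nan
        if self.n_nonsig_replicated == 0:
            return math.inf if self.n_sig_replicated > 0 else math.nan
        return self.pct_sig / self.pct_nonsig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_sig_pairs": self.n_sig_pairs,
                    "n_sig_replicated": self.n_sig_replicated,
                    "pct_sig": self.pct_sig,
                    "n_nonsig_pairs": self.n_nonsig_pairs,
                    "n_nonsig_replicated": self.n_nonsig_replicated,
                    "pct_nonsig": self.pct_nonsig,
                    "relative_ratio": self.relative_ratio,
                    "perm_p": self.perm.p_value if self.perm else math.nan,
                }
            ]
        )


def _validation_lookup(validation: pd.DataFrame) -> tuple[set, dict]:
    """(significant (snp, gene) set, gene -> significant SNP-id set)."""
    sig = validation[validation["significant"].astype(int) == 1]
    pair_set = set(zip(sig["snp_id"], sig["gene_id"]))
    by_gene: dict[str, set[str]] = {}
    for snp, gene in pair_set:
        by_gene.setdefault(gene, set()).add(snp)
    return pair_set, by_gene


def overlap_pairs(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    proxies: dict[str, set[tuple[str, float]]] | None = None,
) -> np.ndarray:
    """Per-discovery-row replicated flag (direct match or same-gene proxy)."""
    if validation.empty:
        warnings.warn("validation table is empty; no pair can replicate", stacklevel=2)
        return np.zeros(len(discovery), dtype=bool)
    pair_set, by_gene = _validation_lookup(validation)
    proxies = proxies or {}
    flags = np.zeros(len(discovery), dtype=bool)
    for i, (snp, gene) in enumerate(zip(discovery["snp_id"], discovery["gene_id"])):
        if (snp, gene) in pair_set:
            flags[i] = True
            continue
        val_snps = by_gene.get(gene)
        if val_snps:
            for proxy_snp, _r2 in proxies.get(snp, ()):
                if proxy_snp != snp and proxy_snp in val_snps:
                    flags[i] = True
                    break
    return flags


def replication_ratio(
    discovery: pd.DataFrame, flags: np.ndarray, fdr_threshold: float = 0.05
) -> ReplicationResult:
    """Stratify replication by discovery significance and form the ratio.

    ``discovery`` should already be restricted to the analysis universe the
    comparison is defined on (SNPs shared between studies, LD-pruned).
    Untested pairs are excluded.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(discovery):
        raise ValueError("flags are not aligned to the discovery table")
    tested = discovery["tested"].to_numpy(dtype=bool) if "tested" in discovery else np.ones(
        len(discovery), dtype=bool
    )
    sig = tested & (discovery["fdr"].to_numpy() < fdr_threshold)
    nonsig = tested & ~sig
    res = ReplicationResult(
        n_sig_pairs=int(sig.sum()),
        n_sig_replicated=int((sig & flags).sum()),
        n_nonsig_pairs=int(nonsig.sum()),
        n_nonsig_replicated=int((nonsig & flags).sum()),
    )
    if res.n_sig_pairs == 0 or res.n_nonsig_pairs == 0:
        warnings.warn("a replication stratum is empty; ratio undefined", stacklevel=2)
    return res


def permute_replication(
    universe_flags: np.ndarray,
    observed: int,
    n_draw: int,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Null distribution of replication overlap for random pair sets.

    Each permutation draws ``n_draw`` pairs uniformly without replacement
    from the discovery pair universe and counts how many replicate (the
    same replication rule as the observed set, so ``universe_flags`` is the
    per-universe-pair replicated flag).  Drawing without replacement and
    counting flagged members is a hypergeometric draw, which is sampled
    directly.
    """
    universe_flags = np.asarray(universe_flags, dtype=bool)
    n_univ = universe_flags.size
    if not 0 < n_draw <= n_univ:
        raise ValueError(f"n_draw must be in [1, {n_univ}], got {n_draw}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n_good = int(universe_flags.sum())
    perm_counts = rng.hypergeometric(n_good, n_univ - n_good, n_draw, size=n_perm)
    b = count_as_extreme(perm_counts, observed)
    return PermutationResult(observed=float(observed), b=b, n_perm=n_perm)


def replicate_study(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    proxies: dict[str, set[tuple[str, float]]] | None = None,
    fdr_threshold: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ReplicationResult:
    """Full replication analysis: flags, stratified ratio, permutation P."""
    tested = discovery[discovery["tested"]].reset_index(drop=True) if "tested" in discovery else discovery
    flags = overlap_pairs(tested, validation, proxies)
    res = replication_ratio(tested, flags, fdr_threshold)
    if res.n_sig_pairs > 0:
        res.perm = permute_replication(
            flags, observed=res.n_sig_replicated, n_draw=res.n_sig_pairs, n_perm=n_perm, seed=seed
        )
    return res
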