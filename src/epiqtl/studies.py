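"""Calibration, power and recovery study harnesses.

These run the full pipeline (simulate -> map -> prune -> replicate ->
enrich) repeatedly under three frozen scenario designs and collect the
statistics that validate the machinery:

* **Null calibration** — no structure couples the GWAS, validation study or
  gene sets to the eQTLs (planted cis effects exist so counts are
  non-degenerate, but flags, replication and gene sets are drawn
  independently of them).  All four permutation P-values must then be
  Uniform(0, 1) and the enrichment folds / ratios center on 1.  The design
  uses a weakly-linked panel and high background rates so overlap counts
  are large; permutation P-values are discrete, and only become
  near-uniform when the overlap statistic has many attainable values.
* **Power** — strong planted coupling (flags drawn at 10:1 odds toward
  planted eQTL SNPs, validation replication 0.5 vs 0.002 background, gene
  sets at 10:1 odds toward true cis-genes) on a 2000-SNP panel; each
  permutation test should reject at alpha = 0.05 in nearly every run.  A
  moderately-linked panel (haplotype copy probability 0.5) is used because
  LD sharing of significance otherwise inflates the baseline eQTL fraction
  and compresses fold enrichments.
* **Recovery** — generator defaults (44 samples, effect 1.5 sd per allele,
  unit noise): planted pairs should be detected at FDR < 0.05 with high
  sensitivity, and the OLS effect estimates should be unbiased.

Each scenario's second "study B" (for the two-study comparisons) is an
independent expression layer simulated on the same genotypes with a
deterministic seed offset.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import cis, genesets, ld
from . import gwas as gw
from .config import SimulationConfig
from .replicate import replicate_study
from .simulate import (
    simulate_cohort,
    simulate_expression,
    simulate_gene_sets,
    simulate_validation_study,
)

#: no GWAS/validation/gene-set coupling; large overlap counts for calibration
NULL_SCENARIO = dict(
    n_chroms=2,
    snps_per_chrom=400,
    n_genes=200,
    frac_true_eqtl_genes=0.5,
    ld_decay=0.3,
    gwas_enrichment_odds=1.0,
    gwas_beta_a=0.01,
    n_gwas_true_snps=280,
    validation_replication_rate=0.5,
    validation_background_rate=0.5,
    geneset_enrichment_odds=1.0,
    n_mendelian_epilepsy_genes=20,
    n_mendelian_other_genes=40,
)

#: strong planted coupling at 10:1 odds on a 2000-SNP panel
POWER_SCENARIO = dict(
    n_chroms=2,
    snps_per_chrom=1000,
    n_genes=400,
    frac_true_eqtl_genes=0.2,
    ld_decay=0.5,
    gwas_enrichment_odds=10.0,
    gwas_beta_a=0.01,
    n_gwas_true_snps=300,
    validation_replication_rate=0.5,
    validation_background_rate=0.002,
    geneset_enrichment_odds=10.0,
    n_mendelian_epilepsy_genes=80,
    n_mendelian_other_genes=160,
)

#: GWAS cutoff at which the planted flags concentrate (Beta(0.01, 1) draws)
GWAS_TEST_THRESHOLD = 1e-4
#: seed offset deriving the independent comparison study from the same cohort
STUDY_B_OFFSET = 500_000


def _map_study(cfg: SimulationConfig) -> dict:
    data = simulate_cohort(cfg)
    pairs = cis.enumerate_cis_pairs(
        data["variants"], data["annotation"], window=cfg.cis_window_bp
    )
    eqtl = cis.fit_cis_model(data["geno"], cis.select_probes(data["expr"]), pairs)
    return {**data, "pairs": pairs, "eqtl": eqtl, "config": cfg}


def run_scenario_once(cfg: SimulationConfig, n_perm: int = 199, seed: int = 0) -> dict:
    """One full pipeline pass; returns every per-run statistic of interest.

    Keys: ``p_replication``, ``p_enrichment``, ``p_compare_enrichment``,
    ``p_compare_genes`` (permutation P-values), ``fold`` (enrichment fold at
    the test threshold), ``relative_ratio`` (replication), ``gene_ratio``
    (Mendelian enrichment of study A), plus ``study`` with the raw tables.
    """
    s = _map_study(cfg)
    geno, variants, ann, truth, eqtl = (
        s["geno"], s["variants"], s["annotation"], s["truth"], s["eqtl"],
    )

    proxies = ld.build_proxy_map(geno, variants)
    pruned = ld.ld_prune(sorted(set(eqtl["snp_id"])), geno, variants)
    disc = eqtl[eqtl["snp_id"].isin(pruned)].reset_index(drop=True)
    validation = simulate_validation_study(truth, eqtl, cfg)
    repl = replicate_study(disc, validation, proxies, n_perm=n_perm, seed=seed)

    shared = gw.shared_pruned_snps(s["gwas"], eqtl, geno, variants)
    perm_enr = gw.permute_enrichment(
        shared, threshold=GWAS_TEST_THRESHOLD, n_perm=n_perm, seed=seed
    )
    curve = gw.enrichment_curve(shared)
    fold = float(
        curve.table.loc[curve.table["threshold"] == GWAS_TEST_THRESHOLD, "fold"].iloc[0]
    )

    # independent comparison study on the same genotype panel
    cfg_b = replace(cfg, seed=cfg.seed + STUDY_B_OFFSET)
    expr_b, _ = simulate_expression(geno, ann, variants, cfg_b)
    eqtl_b = cis.fit_cis_model(geno, cis.select_probes(expr_b), s["pairs"])
    shared_b = gw.shared_pruned_snps(s["gwas"], eqtl_b, geno, variants)
    perm_cmp = gw.compare_enrichment(
        shared, shared_b, threshold=GWAS_TEST_THRESHOLD, n_perm=n_perm, seed=seed
    )

    epilepsy, other = simulate_gene_sets(ann, truth, cfg)
    cis_a = genesets.classify_cis_genes(eqtl)
    cis_b = genesets.classify_cis_genes(eqtl_b)
    gene_res = genesets.mendelian_enrichment(cis_a, epilepsy, other)
    perm_gene = genesets.compare_gene_enrichment(
        cis_a, cis_b, epilepsy, other, n_perm=n_perm, seed=seed
    )

    return {
        "p_replication": repl.perm.p_value if repl.perm else np.nan,
        "p_enrichment": perm_enr.p_value,
        "p_compare_enrichment": perm_cmp.p_value,
        "p_compare_genes": perm_gene.p_value,
        "fold": fold,
        "relative_ratio": repl.relative_ratio,
        "gene_ratio": gene_res.ratio,
        "study": s,
        "replication": repl,
    }


def _scenario_frame(scenario: dict, n_runs: int, base_seed: int, n_perm: int) -> pd.DataFrame:
    rows = []
    for i in range(n_runs):
        cfg = SimulationConfig(seed=base_seed + i, **scenario)
        out = run_scenario_once(cfg, n_perm=n_perm, seed=base_seed + i)
        rows.append({k: out[k] for k in (
            "p_replication", "p_enrichment", "p_compare_enrichment", "p_compare_genes",
            "fold", "relative_ratio", "gene_ratio",
        )})
    return pd.DataFrame(rows)


def null_calibration(n_runs: int = 200, base_seed: int = 3000, n_perm: int = 199) -> pd.DataFrame:
    """Permutation P-values and folds/ratios over null-scenario replicates."""
    return _scenario_frame(NULL_SCENARIO, n_runs, base_seed, n_perm)


def power_study(n_runs: int = 50, base_seed: int = 1000, n_perm: int = 199) -> pd.DataFrame:
    """Permutation P-values and folds/ratios over planted-coupling replicates."""
    return _scenario_frame(POWER_SCENARIO, n_runs, base_seed, n_perm)


def recovery_study(n_runs: int = 20, base_seed: int = 7000) -> pd.DataFrame:
    """Planted-pair sensitivity and effect-estimate errors at generator defaults.

    One row per run with ``sensitivity`` (fraction of planted pairs at
    FDR < 0.05), ``mean_beta_error`` and ``n_planted``.
    """
    rows = []
    for i in range(n_runs):
        cfg = SimulationConfig(seed=base_seed + i)
        s = _map_study(cfg)
        planted = {(snp, gene): beta for snp, gene, beta in s["truth"].true_pairs}
        sub = s["eqtl"].set_index(["snp_id", "gene_id"]).loc[list(planted.keys())]
        errors = sub["beta"].to_numpy() - np.array(list(planted.values()))
        rows.append(
            {
                "sensitivity": float((sub["fdr"] < 0.05).mean()),
                "mean_beta_error": float(errors.mean()),
                "beta_errors": errors,
                "n_planted": len(planted),
            }
        )
    return pd.DataFrame(rows)
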