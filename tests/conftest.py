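import numpy as np
import pandas as pd
import pytest

from epiqtl import cis
from epiqtl.config import SimulationConfig
from epiqtl.simulate import simulate_cohort


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast cohort: 44 samples, 1 chromosome, 120 SNPs, 24 genes."""
    base = dict(
        n_chroms=1,
        snps_per_chrom=120,
        n_genes=24,
        frac_true_eqtl_genes=0.25,
        n_gwas_true_snps=10,
        n_mendelian_epilepsy_genes=5,
        n_mendelian_other_genes=10,
    )
    base.update(overrides)
    return SimulationConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def cohort():
    """One small simulated cohort shared by read-only tests."""
    cfg = small_config(seed=11)
    data = simulate_cohort(cfg)
    data["config"] = cfg
    return data


@pytest.fixture(scope="session")
def mapped(cohort):
    """The shared cohort plus cis pairs and fitted eQTL results."""
    pairs = cis.enumerate_cis_pairs(cohort["variants"], cohort["annotation"])
    eqtl = cis.fit_cis_model(
        cohort["geno"], cis.select_probes(cohort["expr"]), pairs
    )
    return {**cohort, "pairs": pairs, "eqtl": eqtl}


def toy_variants(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": list(positions),
            "maf": 0.3,
        }
    )


def toy_genes(intervals, chrom="chr1"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(intervals))],
            "chrom": chrom,
            "start": [a for a, _ in intervals],
            "end": [b for _, b in intervals],
            "strand": "+",
        }
    )


def ols_oracle(g, y):
    """Closed-form simple-regression oracle: slope, se, t, two-sided p.

    Independent of the package implementation: textbook sums and the
    Student-t survival function only.
    """
    from scipy.stats import t as tdist

    g = np.asarray(g, float)
    y = np.asarray(y, float)
    n = len(g)
    gbar, ybar = g.mean(), y.mean()
    sxx = ((g - gbar) ** 2).sum()
    sxy = ((g - gbar) * (y - ybar)).sum()
    beta = sxy / sxx
    alpha = ybar - beta * gbar
    resid = y - alpha - beta * g
    s2 = (resid**2).sum() / (n - 2)
    se = np.sqrt(s2 / sxx)
    tstat = beta / se
    p = 2 * tdist.sf(abs(tstat), df=n - 2)
    return beta, se, tstat, p
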