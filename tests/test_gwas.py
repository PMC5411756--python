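"""GWAS-eQTL enrichment: shared SNP list, curve, permutations, f2/f1 grid."""

import numpy as np
import pandas as pd
import pytest

from epiqtl import gwas as gw
from epiqtl.containers import GenotypeMatrix
from epiqtl.exceptions import AnalysisError


def _eqtl(rows):
    df = pd.DataFrame(rows, columns=["snp_id", "gene_id", "fdr"])
    df["tested"] = True
    return df


def _gwas(snp_p):
    return pd.DataFrame(
        {
            "snp_id": list(snp_p),
            "chrom": "chr1",
            "pos": np.arange(1, len(snp_p) + 1) * 10_000,
            "p": list(snp_p.values()),
        }
    )


def _indep_geno(n_snps, seed=0, n=40):
    rng = np.random.default_rng(seed)
    D = rng.binomial(2, 0.4, size=(n, n_snps)).astype(float)
    return GenotypeMatrix(
        [f"S{i}" for i in range(n)], [f"rs{j}" for j in range(n_snps)], D
    )


def _variants_for(geno):
    return pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chrom": "chr1",
            "pos": np.arange(1, geno.n_snps + 1) * 10_000,
            "maf": 0.4,
        }
    )


class TestSharedPrunedSnps:
    def test_min_fdr_across_genes_is_kept(self):
        eqtl = _eqtl([("rs0", "gA", 0.2), ("rs0", "gB", 0.01), ("rs0", "gC", 0.8)])
        geno = _indep_geno(1)
        shared = gw.shared_pruned_snps(
            _gwas({"rs0": 0.5}), eqtl, geno, _variants_for(geno), prune=False
        )
        assert shared["min_eqtl_fdr"].tolist() == [0.01]

    def test_disjoint_snp_sets_rejected(self):
        eqtl = _eqtl([("rsX", "gA", 0.2)])
        geno = _indep_geno(1)
        with pytest.raises(AnalysisError):
            gw.shared_pruned_snps(_gwas({"rs0": 0.5}), eqtl, geno, _variants_for(geno))

    def test_unlinked_snps_pass_through_pruning(self):
        geno = _indep_geno(6, seed=3)
        eqtl = _eqtl([(s, "gA", 0.2) for s in geno.snp_ids])
        gwas = _gwas({s: 0.5 for s in geno.snp_ids})
        shared = gw.shared_pruned_snps(gwas, eqtl, geno, _variants_for(geno))
        assert sorted(shared["snp_id"]) == sorted(geno.snp_ids)


def _shared_frame(gwas_p, fdr):
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(len(gwas_p))],
            "gwas_p": gwas_p,
            "min_eqtl_fdr": fdr,
        }
    )


class TestEnrichmentCurve:
    def test_hand_arithmetic_fold(self):
        """1000 SNPs, 10 eQTLs (baseline 0.01); 20 pass P<=0.01, 10 of them
        eQTLs -> fraction 0.5, fold 50."""
        gwas_p = np.ones(1000)
        gwas_p[:20] = 0.005
        fdr = np.full(1000, 0.5)
        fdr[:10] = 0.01
        curve = gw.enrichment_curve(_shared_frame(gwas_p, fdr), thresholds=(1.0, 0.01))
        row = curve.table.set_index("threshold").loc[0.01]
        assert row["fraction"] == pytest.approx(0.5)
        assert row["fold"] == pytest.approx(50.0)
        base = curve.table.set_index("threshold").loc[1.0]
        assert base["fold"] == 1.0

    def test_no_significant_eqtls_rejected(self):
        frame = _shared_frame(np.random.default_rng(0).uniform(size=50), np.full(50, 0.5))
        with pytest.raises(AnalysisError):
            gw.enrichment_curve(frame)

    def test_empty_bin_flagged_undefined(self):
        frame = _shared_frame(np.full(20, 0.5), np.r_[np.full(5, 0.01), np.full(15, 0.5)])
        curve = gw.enrichment_curve(frame, thresholds=(1.0, 1e-6))
        row = curve.table.set_index("threshold").loc[1e-6]
        assert not row["defined"]
        assert np.isnan(row["fraction"])

    def test_missing_baseline_rejected(self):
        frame = _shared_frame(np.full(10, 0.5), np.full(10, 0.01))
        with pytest.raises(ValueError):
            gw.enrichment_curve(frame, thresholds=(0.5, 0.01))

    def test_null_folds_stay_near_one(self):
        """eQTL status independent of GWAS P: folds ~ 1 at lenient cutoffs."""
        folds = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            frame = _shared_frame(rng.uniform(size=500), np.where(rng.random(500) < 0.2, 0.01, 0.5))
            curve = gw.enrichment_curve(frame, thresholds=(1.0, 0.5, 0.1))
            folds.append(curve.table.set_index("threshold").loc[0.1, "fold"])
        assert abs(np.mean(folds) - 1.0) < 0.1


class TestMaxEnrichment:
    def _curve(self, thresholds, folds, ns):
        tbl = pd.DataFrame(
            {
                "threshold": thresholds,
                "n_gwas_snps": ns,
                "n_eqtl": 0,
                "fraction": 0.1,
                "defined": [n > 0 for n in ns],
                "fold": folds,
            }
        )
        return gw.EnrichmentCurve(table=tbl, eqtl_fdr_cut=0.05)

    def test_monotone_folds_pick_most_stringent(self):
        curve = self._curve([1.0, 0.1, 0.01], [1.0, 2.0, 5.0], [100, 50, 20])
        assert gw.max_enrichment(curve, min_bin=10) == (0.01, 5.0)

    def test_flat_curve_ties_to_baseline(self):
        curve = self._curve([1.0, 0.1, 0.01], [1.0, 1.0, 1.0], [100, 50, 20])
        assert gw.max_enrichment(curve, min_bin=10) == (1.0, 1.0)

    def test_small_bins_excluded(self):
        curve = self._curve([1.0, 0.1, 0.01], [1.0, 2.0, 50.0], [100, 50, 3])
        assert gw.max_enrichment(curve, min_bin=10) == (0.1, 2.0)

    def test_all_bins_small_rejected(self):
        curve = self._curve([1.0], [1.0], [5])
        with pytest.raises(AnalysisError):
            gw.max_enrichment(curve, min_bin=10)


class TestPermuteEnrichment:
    def test_extreme_overlap_gets_add_one_pvalue(self):
        gwas_p = np.ones(500)
        gwas_p[:20] = 1e-6
        fdr = np.full(500, 0.5)
        fdr[:20] = 0.001  # all GWAS hits are eQTLs
        res = gw.permute_enrichment(
            _shared_frame(gwas_p, fdr), threshold=1e-4, n_perm=100, seed=0
        )
        assert res.p_value == pytest.approx(1 / 101)
        assert res.bound == pytest.approx(0.01)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        frame = _shared_frame(rng.uniform(size=300), np.where(rng.random(300) < 0.2, 0.01, 0.5))
        r1 = gw.permute_enrichment(frame, threshold=0.1, n_perm=300, seed=5)
        r2 = gw.permute_enrichment(frame, threshold=0.1, n_perm=300, seed=5)
        assert r1 == r2

    def test_agrees_with_explicit_subset_oracle(self):
        rng = np.random.default_rng(2)
        sig = rng.random(400) < 0.25
        gwas_p = rng.uniform(size=400)
        frame = _shared_frame(gwas_p, np.where(sig, 0.01, 0.5))
        res = gw.permute_enrichment(frame, threshold=0.1, n_perm=4000, seed=6)
        at = gwas_p <= 0.1
        observed = int((at & sig).sum())
        oracle_rng = np.random.default_rng(7)
        counts = np.array(
            [sig[oracle_rng.choice(400, int(at.sum()), replace=False)].sum() for _ in range(4000)]
        )
        oracle_p = ((counts >= observed).sum() + 1) / 4001
        assert res.p_value == pytest.approx(oracle_p, abs=0.05)

    def test_no_passing_snps_rejected(self):
        frame = _shared_frame(np.full(50, 0.9), np.full(50, 0.01))
        with pytest.raises(AnalysisError):
            gw.permute_enrichment(frame, threshold=1e-6, n_perm=10, seed=0)


class TestCompareEnrichment:
    def _two_studies(self, seed, coupled):
        rng = np.random.default_rng(seed)
        n = 600
        gwas_p = rng.uniform(size=n)
        flagged = rng.choice(n, 60, replace=False)
        gwas_p[flagged] = rng.beta(0.01, 1.0, size=60)
        sig_a = rng.random(n) < 0.15
        if coupled:
            sig_a[flagged] = rng.random(60) < 0.8
        sig_b = rng.random(n) < 0.15
        a = _shared_frame(gwas_p, np.where(sig_a, 0.01, 0.5))
        b = _shared_frame(gwas_p, np.where(sig_b, 0.01, 0.5))
        return a, b

    def test_identical_studies_are_null(self):
        a, _ = self._two_studies(0, coupled=False)
        res = gw.compare_enrichment(a, a.copy(), threshold=1e-3, n_perm=200, seed=1)
        assert res.observed == 0.0
        assert res.p_value > 0.5

    def test_swapping_studies_negates_the_statistic(self):
        a, b = self._two_studies(2, coupled=True)
        r_ab = gw.compare_enrichment(a, b, threshold=1e-3, n_perm=50, seed=3)
        r_ba = gw.compare_enrichment(b, a, threshold=1e-3, n_perm=50, seed=3)
        assert r_ab.observed == pytest.approx(-r_ba.observed)

    def test_planted_difference_is_detected(self):
        a, b = self._two_studies(4, coupled=True)
        res = gw.compare_enrichment(a, b, threshold=1e-3, n_perm=500, seed=5)
        assert res.p_value < 0.05

    def test_disjoint_universes_rejected(self):
        a, b = self._two_studies(6, coupled=False)
        b = b.assign(snp_id=["x" + s for s in b["snp_id"]])
        with pytest.raises(AnalysisError):
            gw.compare_enrichment(a, b, threshold=1e-3, n_perm=10, seed=0)


class TestReverseEnrichmentGrid:
    def test_hand_arithmetic_cell(self):
        """100 SNPs, 10 with GWAS P < 1e-6 (f1 = 0.1); 20-SNP eQTL subset
        holding 5 of them (f2 = 0.25) -> enrichment 2.5."""
        gwas_p = np.full(100, 0.5)
        fdr = np.full(100, 0.5)
        gwas_p[:5] = 1e-8
        fdr[:20] = 0.01
        gwas_p[20:25] = 1e-8
        grid = gw.reverse_enrichment_grid(
            _shared_frame(gwas_p, fdr), gwas_p_grid=(1e-6,), eqtl_fdr_grid=(0.05,)
        )
        row = grid.table.iloc[0]
        assert row["f1"] == pytest.approx(0.1)
        assert row["f2"] == pytest.approx(0.25)
        assert row["relative_enrichment"] == pytest.approx(2.5)

    def test_zero_f1_is_undefined_not_divided(self):
        grid = gw.reverse_enrichment_grid(
            _shared_frame(np.full(50, 0.5), np.full(50, 0.01)),
            gwas_p_grid=(1e-6,),
            eqtl_fdr_grid=(0.05,),
        )
        row = grid.table.iloc[0]
        assert not row["defined"]
        assert np.isnan(row["relative_enrichment"])

    def test_matches_counting_oracle_exactly(self):
        """f1/f2 equal a brute-force two-pass counting oracle on every cell."""
        rng = np.random.default_rng(8)
        gwas_p = rng.uniform(size=2000) ** 3
        fdr = rng.uniform(size=2000)
        p_grid, f_grid = (0.5, 0.01, 1e-4), (0.01, 0.05, 0.2)
        grid = gw.reverse_enrichment_grid(_shared_frame(gwas_p, fdr), p_grid, f_grid).table
        for p_cut in p_grid:
            for fdr_cut in f_grid:
                f1 = sum(1 for p in gwas_p if p < p_cut) / 2000
                sub = [p for p, f in zip(gwas_p, fdr) if f < fdr_cut]
                f2 = (sum(1 for p in sub if p < p_cut) / len(sub)) if sub else np.nan
                row = grid[(grid["p_cut"] == p_cut) & (grid["fdr_cut"] == fdr_cut)].iloc[0]
                assert row["f1"] == f1
                if sub:
                    assert row["f2"] == f2
                    if f1 > 0:
                        assert row["relative_enrichment"] == f2 / f1

    def test_random_eqtl_subset_centers_on_one(self):
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            frame = _shared_frame(rng.uniform(size=400), rng.uniform(size=400))
            grid = gw.reverse_enrichment_grid(frame, (0.2,), (0.3,)).table
            vals.append(grid["relative_enrichment"].iloc[0])
        assert abs(np.nanmean(vals) - 1.0) < 0.1
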