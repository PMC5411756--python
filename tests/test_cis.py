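"""cis-eQTL mapping: window rule, probe selection, OLS oracle, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import ols_oracle, toy_genes, toy_variants

from epiqtl import cis
from epiqtl.containers import ExpressionMatrix, GenotypeMatrix
from epiqtl.exceptions import AnalysisError, DataConsistencyError


class TestEnumerateCisPairs:
    GENES = toy_genes([(10_000, 12_000)])

    def _pairs(self, positions, chrom="chr1", window=20_000):
        return cis.enumerate_cis_pairs(toy_variants(positions, chrom), self.GENES, window)

    def test_snp_inside_gene_body_has_distance_zero(self):
        pairs = self._pairs([10_500])
        assert len(pairs) == 1
        assert pairs["distance"].iloc[0] == 0

    def test_window_boundary_is_inclusive(self):
        # 32 000 is exactly 20 kb from the gene end (12 000); 32 001 is out
        pairs = self._pairs([32_000, 32_001])
        assert pairs["snp_id"].tolist() == ["rs0"]
        assert pairs["distance"].iloc[0] == 20_000

    def test_upstream_boundary_also_inclusive(self):
        pairs = self._pairs([1, 9_999])
        got = dict(zip(pairs["snp_id"], pairs["distance"]))
        assert got == {"rs0": 9_999, "rs1": 1}

    def test_other_chromosome_never_pairs(self):
        with pytest.warns(UserWarning, match="skipped"):
            pairs = self._pairs([10_500], chrom="chr2")
        assert pairs.empty

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            self._pairs([10_500], window=-1)


def _expr(values, probe_to_gene, samples=None):
    values = np.asarray(values, float)
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(samples, list(probe_to_gene), values, dict(probe_to_gene))


class TestSelectProbes:
    def test_highest_variance_probe_retained(self):
        rng = np.random.default_rng(0)
        vals = np.column_stack([rng.normal(0, 1.2, 20), rng.normal(0, 0.3, 20)])
        expr = _expr(vals, {"pa": "g1", "pb": "g1"})
        kept = cis.select_probes(expr)
        winner = "pa" if vals[:, 0].var(ddof=1) > vals[:, 1].var(ddof=1) else "pb"
        assert kept.probe_ids == [winner]

    def test_single_probe_gene_passes_through(self):
        expr = _expr(np.random.default_rng(1).normal(size=(10, 1)), {"pa": "g1"})
        assert cis.select_probes(expr).probe_ids == ["pa"]

    def test_exact_tie_breaks_lexicographically(self):
        col = np.arange(10.0)
        expr = _expr(np.column_stack([col, col]), {"pz": "g1", "pa": "g1"})
        assert cis.select_probes(expr).probe_ids == ["pa"]


class TestResidualize:
    def test_no_covariates_mean_centers(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.normal(2.0, 1.0, size=(15, 3)), {"a": "g1", "b": "g2", "c": "g3"})
        cov = pd.DataFrame(index=expr.sample_ids)
        out = cis.residualize_covariates(expr, cov)
        np.testing.assert_allclose(out.values, expr.values - expr.values.mean(0), atol=1e-12)

    def test_perfect_covariate_zeroes_residuals(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=15)
        expr = _expr(y[:, None], {"a": "g1"})
        cov = pd.DataFrame({"x": y}, index=expr.sample_ids)
        out = cis.residualize_covariates(expr, cov)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.normal(size=(30, 4)), {p: f"g{p}" for p in "abcd"})
        cov = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("xyz"), index=expr.sample_ids)
        out = cis.residualize_covariates(expr, cov)
        for c in cov.columns:
            inner = out.values.T @ cov[c].to_numpy()
            np.testing.assert_allclose(inner, 0.0, atol=1e-8)

    def test_collinear_covariates_named_in_error(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        cov = pd.DataFrame({"x": x, "x_copy": 2 * x})
        expr = _expr(rng.normal(size=(20, 1)), {"a": "g1"})
        with pytest.raises(DataConsistencyError, match="x_copy"):
            cis.residualize_covariates(expr, cov)


def _pair_table(snps, genes):
    return pd.DataFrame({"snp_id": snps, "gene_id": genes, "distance": 0})


class TestFitCisModel:
    def _fit_one(self, g, y):
        g = np.asarray(g, float)
        geno = GenotypeMatrix([f"S{i}" for i in range(len(g))], ["rs0"], g[:, None])
        expr = _expr(np.asarray(y, float)[:, None], {"p0": "g0"}, geno.sample_ids)
        return cis.fit_cis_model(geno, expr, _pair_table(["rs0"], ["g0"])).iloc[0]

    def test_noiseless_fit_recovers_slope_with_floored_p(self):
        g = [0, 0, 1, 1, 2, 2]
        y = 3 + 0.5 * np.asarray(g, float)
        row = self._fit_one(g, y)
        assert row["beta"] == pytest.approx(0.5, abs=1e-12)
        assert row["p"] == cis.P_FLOOR

    def test_monomorphic_dosage_flagged_untested(self):
        # second, polymorphic pair keeps the table testable overall
        g = np.array([[1, 0], [1, 1], [1, 2], [1, 0], [1, 1], [1, 2]], float)
        geno = GenotypeMatrix([f"S{i}" for i in range(6)], ["rs0", "rs1"], g)
        y = np.array([1.0, 2.0, 1.5, 0.5, 1.1, 0.9])
        expr = _expr(np.column_stack([y, y]), {"p0": "g0", "p1": "g1"}, geno.sample_ids)
        res = cis.fit_cis_model(geno, expr, _pair_table(["rs0", "rs1"], ["g0", "g1"]))
        assert not res.iloc[0]["tested"]
        assert np.isnan(res.iloc[0]["beta"])
        assert res.iloc[1]["tested"]

    def test_eight_sample_instance_matches_closed_form(self):
        g = [0, 1, 2, 0, 1, 2, 0, 1]
        y = [1.0, 1.3, 2.1, 0.9, 1.6, 1.8, 1.2, 1.4]
        row = self._fit_one(g, y)
        beta, se, t, p = ols_oracle(g, y)
        assert row["beta"] == pytest.approx(beta, rel=1e-12)
        assert row["se"] == pytest.approx(se, rel=1e-12)
        assert row["t"] == pytest.approx(t, rel=1e-12)
        assert row["p"] == pytest.approx(p, rel=1e-12)

    def test_matches_oracle_on_random_instances(self):
        """100 random pairs: slope/se/t/p within 1e-10 relative of the oracle."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = rng.integers(8, 44)
            g = rng.integers(0, 3, n).astype(float)
            if g.min() == g.max():
                continue
            y = 0.4 * g + rng.normal(0, 1, n)
            row = self._fit_one(g, y)
            beta, se, t, p = ols_oracle(g, y)
            assert row["beta"] == pytest.approx(beta, rel=1e-10)
            assert row["se"] == pytest.approx(se, rel=1e-10)
            assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_missing_dosages_use_complete_cases(self):
        g = np.array([0, 1, 2, np.nan, 1, 0, 2, 1], float)
        y = np.array([0.1, 1.2, 2.3, 9.9, 0.8, 0.2, 1.9, 1.1])
        geno = GenotypeMatrix([f"S{i}" for i in range(8)], ["rs0"], g[:, None])
        expr = _expr(y[:, None], {"p0": "g0"}, geno.sample_ids)
        row = cis.fit_cis_model(geno, expr, _pair_table(["rs0"], ["g0"])).iloc[0]
        ok = ~np.isnan(g)
        beta, se, _, p = ols_oracle(g[ok], y[ok])
        assert row["n_used"] == 7
        assert row["beta"] == pytest.approx(beta, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_too_few_samples_flagged_untested(self):
        g = np.array(
            [[0, 0], [1, 1], [2, 2], [np.nan, 0], [np.nan, 1], [np.nan, 2]], float
        )
        geno = GenotypeMatrix([f"S{i}" for i in range(6)], ["rs0", "rs1"], g)
        y = np.arange(6.0)
        expr = _expr(np.column_stack([y, y]), {"p0": "g0", "p1": "g1"}, geno.sample_ids)
        res = cis.fit_cis_model(geno, expr, _pair_table(["rs0", "rs1"], ["g0", "g1"]))
        assert not res.iloc[0]["tested"]  # only 3 complete cases
        assert res.iloc[1]["tested"]

    def test_all_untested_raises(self):
        geno = GenotypeMatrix([f"S{i}" for i in range(6)], ["rs0"], np.ones((6, 1)))
        expr = _expr(np.arange(6.0)[:, None], {"p0": "g0"}, geno.sample_ids)
        with pytest.raises(AnalysisError):
            cis.fit_cis_model(geno, expr, _pair_table(["rs0"], ["g0"]))


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2], [0.2]),
            ([0.005, 0.9], [0.01, 0.9]),
        ],
    )
    def test_hand_worked_examples(self, p, expected):
        np.testing.assert_allclose(cis.bh_fdr(p), expected, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cis.bh_fdr([0.5, 1.2])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_invariants(self, p):
        q = cis.bh_fdr(p)
        p_arr = np.asarray(p)
        assert (q >= p_arr - 1e-15).all()
        assert (q <= 1.0).all()
        # q monotone in p-rank
        order = np.argsort(p_arr, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        # invariant to input permutation
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        np.testing.assert_allclose(cis.bh_fdr(p_arr[perm]), q[perm], rtol=1e-12)

    def test_matches_statsmodels(self):
        """Independent cross-check against statsmodels' BH implementation."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(cis.bh_fdr(p), q_sm, rtol=1e-10)


class TestStratificationCheck:
    def test_two_population_structure_is_detected(self):
        """Two genotype clusters with shifted expression: PC1 flags probes."""
        rng = np.random.default_rng(8)
        n, m, k = 40, 60, 30
        pop = np.repeat([0, 1], n // 2)
        freqs = np.where(pop[:, None] == 0, 0.1, 0.8)  # allele freq differs by cluster
        D = rng.binomial(2, freqs, size=(n, m))
        geno = GenotypeMatrix([f"S{i}" for i in range(n)], [f"rs{j}" for j in range(m)], D.astype(float))
        E = rng.normal(size=(n, k)) + 2.0 * pop[:, None]
        expr = _expr(E, {f"p{j}": f"g{j}" for j in range(k)}, geno.sample_ids)
        rep = cis.stratification_check(geno, expr, n_pcs=5)
        bonferroni = 0.05 / (5 * k)
        assert rep.loc[rep["pc"] == 1, "min_p"].iloc[0] < bonferroni

    def test_unstructured_data_is_calibrated(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n, m, k = 30, 50, 40
            D = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            geno = GenotypeMatrix(
                [f"S{i}" for i in range(n)], [f"rs{j}" for j in range(m)], D
            )
            expr = _expr(
                rng.normal(size=(n, k)), {f"p{j}": f"g{j}" for j in range(k)}, geno.sample_ids
            )
            rep = cis.stratification_check(geno, expr, n_pcs=5)
            fracs.append(rep["frac_p_lt_05"].mean())
        assert abs(np.mean(fracs) - 0.05) < 0.03

    def test_too_many_pcs_rejected(self):
        rng = np.random.default_rng(9)
        D = rng.binomial(2, 0.4, size=(10, 20)).astype(float)
        geno = GenotypeMatrix([f"S{i}" for i in range(10)], [f"rs{j}" for j in range(20)], D)
        expr = _expr(rng.normal(size=(10, 3)), {f"p{j}": f"g{j}" for j in range(3)}, geno.sample_ids)
        with pytest.raises(ValueError):
            cis.stratification_check(geno, expr, n_pcs=10)
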