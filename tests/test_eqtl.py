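"""Pseudobulk eQTL machinery: normalization, HWE, pruning, OLS, cFDR."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.special import gammaln

from cellink.eqtl import (
    EqtlConfig,
    aggregate_pseudobulk,
    conditional_fdr,
    expression_pcs,
    hwe_exact_test,
    ld_prune,
    map_cis_eqtl,
    normalize_cells,
    variant_qc,
)
from cellink.eqtl import test_interaction as interaction_test
from cellink.io import GenotypeMatrix
from cellink.synth import SimConfig, sim_genotypes


def _adata(counts, donors=None, cell_type=None):
    counts = np.asarray(counts, dtype=float)
    obs = pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])])
    if donors is not None:
        obs["donor"] = donors
    if cell_type is not None:
        obs["cell_type"] = cell_type
    var = pd.DataFrame(index=[f"g{j}" for j in range(counts.shape[1])])
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


class TestNormalize:
    def test_size_factors_from_definition(self):
        adata = _adata([[100, 0], [0, 300]])
        out = normalize_cells(adata)
        np.testing.assert_allclose(out.obs["size_factor"], [0.5, 1.5])

    def test_identical_cells_reduce_to_log1p(self):
        adata = _adata([[5, 10, 1]] * 4)
        out = normalize_cells(adata)
        np.testing.assert_allclose(out.obs["size_factor"], 1.0)
        np.testing.assert_allclose(out.X.toarray(), np.log1p([[5, 10, 1]] * 4))

    def test_size_factors_invariant_to_global_depth_scaling(self):
        # the unit-mean definition makes factors depend only on relative
        # depth; doubling every count doubles the normalized linear values
        base = np.array([[3, 7, 0], [10, 0, 5], [1, 1, 1]], dtype=float)
        a = normalize_cells(_adata(base))
        b = normalize_cells(_adata(2 * base))
        np.testing.assert_allclose(
            b.obs["size_factor"], a.obs["size_factor"], atol=1e-12
        )
        np.testing.assert_allclose(
            np.expm1(b.X.toarray()), 2 * np.expm1(a.X.toarray()), atol=1e-9
        )

    def test_all_zero_cell_error_names_cell(self):
        with pytest.raises(ValueError, match="c1"):
            normalize_cells(_adata([[1, 2], [0, 0]]))


class TestPseudobulk:
    def test_mean_of_two_cells(self):
        adata = _adata([[1.0], [3.0]], donors=["d1", "d1"], cell_type=["Oli", "Oli"])
        pb = aggregate_pseudobulk(adata, "Oli")
        assert pb.loc["d1", "g0"] == pytest.approx(2.0)

    def test_donor_without_cells_excluded_not_imputed(self):
        adata = _adata([[1.0], [3.0]], donors=["d1", "d2"],
                       cell_type=["Oli", "Ast"])
        pb = aggregate_pseudobulk(adata, "Oli")
        assert list(pb.index) == ["d1"]
        assert pb.attrs["excluded_donors"] == ["d2"]

    def test_cell_order_invariance(self, small_cells):
        norm = normalize_cells(small_cells)
        pb1 = aggregate_pseudobulk(norm)
        perm = np.random.default_rng(1).permutation(norm.n_obs)
        pb2 = aggregate_pseudobulk(norm[perm].copy())
        pd.testing.assert_frame_equal(pb1, pb2)

    def test_unknown_cell_type_error(self):
        adata = _adata([[1.0]], donors=["d1"], cell_type=["Oli"])
        with pytest.raises(ValueError, match="unknown cell type"):
            aggregate_pseudobulk(adata, "Neuron")


def hwe_oracle(n0, n1, n2):
    """Independent full enumeration with exact conditional probabilities."""
    n = n0 + n1 + n2
    rare = min(2 * n2 + n1, 2 * n0 + n1)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        logp = (
            gammaln(n + 1) - gammaln(hr + 1) - gammaln(h + 1) - gammaln(hc + 1)
            + h * np.log(2)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
        )
        probs[h] = np.exp(logp)
    total = sum(probs.values())
    p_obs = probs[n1] / total
    return min(sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12)), 1.0)


class TestHwe:
    def test_worked_example_two_homozygote_classes(self):
        # counts (2, 0, 2): het in {0, 2, 4} with probs 6/70, 48/70, 16/70
        assert hwe_exact_test(2, 0, 2) == pytest.approx(6 / 70, abs=1e-12)

    def test_monomorphic_is_certain(self):
        assert hwe_exact_test(25, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(5, 5, 5), (1, 8, 1), (10, 0, 1),
                                        (0, 3, 7), (12, 4, 14), (3, 3, 0)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


from hypothesis import assume, given, settings  # noqa: E402
from hypothesis import strategies as st  # noqa: E402


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
def test_hwe_is_valid_probability_and_matches_enumeration(n0, n1, n2):
    """For any genotype configuration the exact test returns a probability
    in (0, 1] equal to the independent enumeration oracle."""
    assume(n0 + n1 + n2 >= 1)
    p = hwe_exact_test(n0, n1, n2)
    assert 0 < p <= 1
    assert p == pytest.approx(hwe_oracle(n0, n1, n2), abs=1e-12)


class TestVariantQc:
    def test_maf_arithmetic(self):
        dos = pd.DataFrame({"v1": [0.0, 1.0, 2.0, 2.0]}, index=list("abcd"))
        var = pd.DataFrame({"variant": ["v1"], "chrom": ["chr1"], "pos": [100],
                            "ref": ["A"], "alt": ["G"]})
        _, rec = variant_qc(GenotypeMatrix(dos, var))
        assert rec.loc[0, "maf"] == pytest.approx(0.375)
        assert bool(rec.loc[0, "pass_qc"])

    def test_missing_rate_filter(self):
        vals = np.ones(100)
        vals[:15] = np.nan
        rng = np.random.default_rng(0)
        vals[15:] = rng.integers(0, 3, 85)
        dos = pd.DataFrame({"v1": vals}, index=[f"d{i}" for i in range(100)])
        var = pd.DataFrame({"variant": ["v1"], "chrom": ["chr1"], "pos": [1],
                            "ref": ["A"], "alt": ["C"]})
        _, rec = variant_qc(GenotypeMatrix(dos, var))
        assert rec.loc[0, "missing_rate"] == pytest.approx(0.15)
        assert not bool(rec.loc[0, "pass_qc"])

    def test_all_missing_variant_removed_without_numeric_error(self):
        dos = pd.DataFrame({"v1": [np.nan] * 5, "v2": [0, 1, 1, 2, 0.0]},
                           index=list("abcde"))
        var = pd.DataFrame({"variant": ["v1", "v2"], "chrom": "chr1",
                            "pos": [1, 2], "ref": "A", "alt": "G"})
        kept, rec = variant_qc(GenotypeMatrix(dos, var))
        assert rec.loc[0, "missing_rate"] == 1.0
        assert not bool(rec.loc[0, "pass_qc"])
        assert kept.n_variants == 1

    def test_planted_failures_match_independent_rule_oracle(self, small_geno):
        kept, rec = variant_qc(small_geno, maf_min=0.2, max_missing=0.1, hwe_min_p=1e-6)
        for row in rec.itertuples(index=False):
            col = small_geno.dosages[row.variant]
            obs = col.dropna()
            f = obs.mean() / 2
            maf = min(f, 1 - f)
            counts = [(obs == g).sum() for g in (0, 1, 2)]
            expect = (maf >= 0.2) and (1 - len(obs) / len(col) <= 0.1) and (
                hwe_oracle(*counts) >= 1e-6
            )
            assert row.pass_qc == expect


class TestLdPrune:
    def _geno(self, cols, positions):
        dos = pd.DataFrame(
            {f"v{j}": c for j, c in enumerate(cols)},
            index=[f"d{i}" for i in range(len(cols[0]))],
        )
        var = pd.DataFrame({"variant": [f"v{j}" for j in range(len(cols))],
                            "chrom": "chr1", "pos": positions,
                            "ref": "A", "alt": "G"})
        return GenotypeMatrix(dos, var)

    def test_perfectly_correlated_pair_keeps_first_by_position(self):
        x = [0, 1, 2, 0, 1, 2, 1, 1]
        g = self._geno([x, x], [100, 200])
        assert ld_prune(g) == ["v0"]

    def test_uncorrelated_variants_all_kept(self, rng):
        cols = [rng.integers(0, 3, 200) for _ in range(5)]
        g = self._geno(cols, [100, 200, 300, 400, 500])
        assert len(ld_prune(g, r2_threshold=0.2)) == 5

    def test_no_kept_pair_within_window_exceeds_threshold(self):
        g = sim_genotypes(SimConfig(n_donors=300, n_variants=40, ld_decay=0.9, seed=10))
        kept = ld_prune(g, r2_threshold=0.5, window=10**7)
        d = g.dosages[kept].to_numpy()
        r = np.corrcoef(d.T)
        np.fill_diagonal(r, 0)
        assert (r**2).max() <= 0.5 + 1e-9

    def test_outside_window_correlation_ignored(self):
        x = [0, 1, 2, 0, 1, 2, 1, 1]
        g = self._geno([x, x], [100, 600_000])
        assert ld_prune(g, window=250_000) == ["v0", "v1"]


class TestExpressionPcs:
    def test_rank_one_matrix_single_component(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=8)
        pb = pd.DataFrame(np.outer(u, v) + 5.0)
        pcs = expression_pcs(pb, 2)
        total_var = pcs.to_numpy().var(axis=0, ddof=0)
        assert total_var[1] / total_var[0] < 1e-20

    def test_sign_convention_deterministic(self, rng):
        pb = pd.DataFrame(rng.normal(size=(30, 12)))
        a = expression_pcs(pb, 4)
        b = expression_pcs(pb.copy(), 4)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_gene_dropped_with_warning(self, rng):
        pb = pd.DataFrame(rng.normal(size=(10, 5)))
        pb[0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            expression_pcs(pb, 2)

    def test_k_bound_enforced(self, rng):
        pb = pd.DataFrame(rng.normal(size=(6, 4)))
        with pytest.raises(ValueError):
            expression_pcs(pb, 4)


def _single_variant_geno(pos, dosages, donors):
    dos = pd.DataFrame({"v1": dosages}, index=donors)
    var = pd.DataFrame({"variant": ["v1"], "chrom": ["chr1"], "pos": [pos],
                        "ref": ["A"], "alt": ["G"]})
    return GenotypeMatrix(dos, var)


class TestMapCisEqtl:
    GENES = pd.DataFrame({"gene_id": ["g0"], "chrom": ["chr1"],
                          "start": [1_000_000], "end": [1_005_000]})

    def _pb(self, values, donors):
        return pd.DataFrame({"g0": values}, index=pd.Index(donors, name="donor"))

    @pytest.mark.parametrize("pos,expected_tested", [
        (1_254_999, True),   # distance 249,999 <= 250,000
        (1_255_000, True),   # exactly at the window edge (inclusive)
        (1_255_001, False),  # one bp beyond
        (749_999, False),    # beyond upstream edge
        (750_000, True),     # exactly window upstream of start
    ])
    def test_cis_window_boundary_inclusive(self, rng, pos, expected_tested):
        donors = [f"d{i}" for i in range(30)]
        dosages = rng.integers(0, 3, 30).astype(float)
        geno = _single_variant_geno(pos, dosages, donors)
        pb = self._pb(rng.normal(size=30), donors)
        res = map_cis_eqtl(pb, geno, self.GENES,
                           config=EqtlConfig(n_expression_pcs=0))
        assert (len(res) == 1) == expected_tested

    def test_noise_free_dosage_expression_recovers_unit_slope(self):
        donors = [f"d{i}" for i in range(24)]
        dosages = np.tile([0.0, 1.0, 2.0], 8)
        geno = _single_variant_geno(1_000_500, dosages, donors)
        pb = self._pb(dosages.copy(), donors)
        res = map_cis_eqtl(pb, geno, self.GENES, config=EqtlConfig(n_expression_pcs=0))
        assert res.loc[0, "beta"] == pytest.approx(1.0, abs=1e-12)
        assert res.loc[0, "p"] < 1e-100

    def test_agrees_with_statsmodels_ols_oracle(self, rng):
        import statsmodels.api as sm

        donors = [f"d{i}" for i in range(60)]
        dosages = rng.integers(0, 3, 60).astype(float)
        covar = pd.DataFrame({"age": rng.normal(80, 5, 60),
                              "sex": rng.integers(0, 2, 60)},
                             index=donors)
        y = 0.4 * dosages + 0.05 * covar["age"].to_numpy() + rng.normal(0, 1, 60)
        geno = _single_variant_geno(1_001_000, dosages, donors)
        res = map_cis_eqtl(self._pb(y, donors), geno, self.GENES, covars=covar,
                           config=EqtlConfig(n_expression_pcs=0))
        X = sm.add_constant(np.column_stack([dosages, covar.to_numpy()]))
        fit = sm.OLS(y, X).fit()
        assert res.loc[0, "beta"] == pytest.approx(fit.params[1], abs=1e-8)
        assert res.loc[0, "se"] == pytest.approx(fit.bse[1], abs=1e-8)
        assert res.loc[0, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_constant_dosage_pair_skipped_with_reason(self, rng):
        donors = [f"d{i}" for i in range(20)]
        geno = _single_variant_geno(1_001_000, np.ones(20), donors)
        res = map_cis_eqtl(self._pb(rng.normal(size=20), donors), geno, self.GENES,
                           config=EqtlConfig(n_expression_pcs=0))
        assert len(res) == 0
        assert res.attrs["skipped"].loc[0, "reason"] == "singular_design"

    def test_donor_order_invariance(self, rng):
        donors = [f"d{i}" for i in range(40)]
        dosages = rng.integers(0, 3, 40).astype(float)
        y = 0.5 * dosages + rng.normal(0, 1, 40)
        geno = _single_variant_geno(1_001_000, dosages, donors)
        pb = self._pb(y, donors)
        res1 = map_cis_eqtl(pb, geno, self.GENES, config=EqtlConfig(n_expression_pcs=0))
        perm = rng.permutation(40)
        res2 = map_cis_eqtl(pb.iloc[perm], geno, self.GENES,
                            config=EqtlConfig(n_expression_pcs=0))
        assert res1.loc[0, "beta"] == pytest.approx(res2.loc[0, "beta"], abs=1e-12)


class TestInteraction:
    def test_noise_free_construction(self):
        # expression = dosage among cases, constant 0 in controls
        dose = np.tile([0.0, 1.0, 2.0], 10)
        dx = np.repeat([0.0, 1.0], 15)
        expr = np.where(dx == 1, dose, 0.0)
        out = interaction_test(expr, dose, dx)
        assert out["beta_int"] == pytest.approx(1.0, abs=1e-10)
        assert out["beta_dose"] == pytest.approx(0.0, abs=1e-10)

    def test_identical_slopes_give_null_interaction(self, rng):
        dose = rng.integers(0, 3, 200).astype(float)
        dx = rng.integers(0, 2, 200).astype(float)
        expr = 0.7 * dose + rng.normal(0, 1, 200)
        out = interaction_test(expr, dose, dx)
        assert abs(out["beta_int"]) < 0.5
        assert out["p"] > 1e-4

    def test_permuted_diagnosis_p_roughly_uniform(self, rng):
        dose = rng.integers(0, 3, 100).astype(float)
        expr = 0.5 * dose + rng.normal(0, 1, 100)
        ps = []
        for _ in range(200):
            dx = rng.permutation(np.repeat([0.0, 1.0], 50))
            ps.append(interaction_test(expr, dose, dx)["p"])
        ps = np.array(ps)
        assert abs(np.mean(ps) - 0.5) < 0.08
        assert abs((ps < 0.25).mean() - 0.25) < 0.1

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            interaction_test(np.ones(10), np.arange(10.0), np.zeros(10))


class TestConditionalFdr:
    def test_direct_evaluation_fixture(self):
        # pair 0: p=0.01, aux rank 50 of 100, 10 joint pairs (incl. itself)
        rng = np.random.default_rng(12)
        p = np.empty(100)
        aux = np.empty(100)
        p[0], aux[0] = 0.01, 0.5
        # 49 other pairs with aux below 0.5: 9 with p below 0.01
        aux[1:50] = rng.uniform(0.01, 0.49, 49)
        p[1:10] = rng.uniform(0.001, 0.009, 9)
        p[10:50] = rng.uniform(0.02, 1.0, 40)
        # 50 pairs with aux above 0.5
        aux[50:] = rng.uniform(0.51, 1.0, 50)
        p[50:] = rng.uniform(0.02, 1.0, 50)
        cfdr = conditional_fdr(p, aux)
        assert cfdr[0] == pytest.approx(0.01 * 50 / 10, abs=1e-12)

    def test_uninformative_auxiliary_reduces_to_unconditional(self, rng):
        p = rng.uniform(size=200)
        aux = np.full(200, 0.5)
        cfdr = conditional_fdr(p, aux)
        # p / ecdf(p), monotonized upward in p (single aux stratum)
        n = len(p)
        raw = p * n / np.array([np.sum(p <= pi) for pi in p])
        order = np.argsort(p)
        expected = np.empty(n)
        expected[order] = np.maximum.accumulate(np.minimum(raw[order], 1.0))
        np.testing.assert_allclose(cfdr, expected, atol=1e-12)

    def test_shared_signal_enrichment_beats_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        # 50 true signals with small p in both studies + 450 nulls
        p = np.concatenate([rng.uniform(1e-6, 1e-3, 50), rng.uniform(size=450)])
        aux = np.concatenate([rng.uniform(1e-6, 1e-3, 50), rng.uniform(size=450)])
        cfdr = conditional_fdr(p, aux)
        bh = multipletests(p, method="fdr_bh")[1]
        assert cfdr[:50].mean() < bh[:50].mean()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            conditional_fdr(np.array([0.5]), np.array([0.5, 0.2]))
        with pytest.raises(ValueError):
            conditional_fdr(np.array([0.0]), np.array([0.5]))
        assert conditional_fdr(np.empty(0), np.empty(0)).size == 0
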