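"""Donor-collapsed enrichment, set overlap, windows, trait regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from cellink.enrich import (
    DonorMembership,
    categorical_enrichment,
    collapse_to_donors,
    detection_share,
    genotype_trait_assoc,
    last_measurement_before_death,
    quantitative_enrichment,
    set_overlap_enrichment,
)


class TestCollapse:
    def test_each_contributing_donor_counted_once(self):
        meta = pd.DataFrame({
            "donor": ["d1"] * 500 + ["d2"],
            "cluster": ["c1"] * 501,
        })
        mem = collapse_to_donors(meta)["c1"]
        assert mem.members == {"d1", "d2"}

    def test_min_cell_threshold_excludes_sparse_donor(self):
        meta = pd.DataFrame({
            "donor": ["d1"] * 500 + ["d2"],
            "cluster": ["c1"] * 501,
        })
        mem = collapse_to_donors(meta, min_cells=10)["c1"]
        assert mem.members == {"d1"}

    def test_membership_subset_invariant(self):
        with pytest.raises(ValueError):
            DonorMembership(cluster="x", members={"a"}, cohort={"b"})


def fisher_oracle_two_sided(a, b, c, d):
    """Full hypergeometric enumeration over tables with fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return sum(
        hypergeom.pmf(x, n, col1, row1)
        for x in range(lo, hi + 1)
        if hypergeom.pmf(x, n, col1, row1) <= p_obs * (1 + 1e-9)
    )


class TestCategorical:
    def _membership(self, members, cohort):
        return {"c1": DonorMembership("c1", set(members), set(cohort))}

    def test_odds_ratio_arithmetic(self):
        # table [[10, 10], [10, 70]] -> OR 7
        cohort = [f"d{i}" for i in range(100)]
        members = cohort[:20]
        trait = pd.Series(False, index=cohort)
        trait[cohort[:10]] = True          # 10 members with trait
        trait[cohort[20:30]] = True        # 10 non-members with trait
        res = categorical_enrichment(self._membership(members, cohort), trait)[0]
        assert res.statistic == pytest.approx(7.0)

    def test_p_matches_hypergeometric_enumeration(self):
        cohort = [f"d{i}" for i in range(100)]
        members = cohort[:20]
        trait = pd.Series(False, index=cohort)
        trait[cohort[:10]] = True
        trait[cohort[20:30]] = True
        res = categorical_enrichment(self._membership(members, cohort), trait)[0]
        assert res.p == pytest.approx(fisher_oracle_two_sided(10, 10, 10, 70), abs=1e-9)

    def test_null_membership_p_roughly_uniform(self, rng):
        cohort = [f"d{i}" for i in range(60)]
        trait = pd.Series(rng.random(60) < 0.4, index=cohort)
        ps = []
        for _ in range(300):
            members = rng.choice(cohort, 20, replace=False)
            res = categorical_enrichment(self._membership(members, cohort), trait)[0]
            ps.append(res.p)
        # Fisher p is discrete and conservative; check no inflation
        assert np.mean(np.array(ps) <= 0.05) <= 0.07

    def test_degenerate_memberships_flagged(self):
        cohort = ["a", "b", "c"]
        trait = pd.Series([True, False, True], index=cohort)
        res = categorical_enrichment(
            {"full": DonorMembership("full", set(cohort), set(cohort)),
             "empty": DonorMembership("empty", set(), set(cohort))}, trait)
        assert all(r.degenerate and r.p == 1.0 for r in res)

    def test_fdr_corrected_across_clusters(self, rng):
        cohort = [f"d{i}" for i in range(40)]
        trait = pd.Series(rng.random(40) < 0.5, index=cohort)
        mems = {
            f"c{j}": DonorMembership(f"c{j}", set(rng.choice(cohort, 10, replace=False)),
                                     set(cohort))
            for j in range(5)
        }
        res = categorical_enrichment(mems, trait)
        assert all(r.fdr is not None and r.fdr >= r.p - 1e-12 for r in res)


class TestQuantitative:
    def test_exhaustive_enumeration_fixture(self):
        # members {2, 4} of cohort {1,2,3,4}: null mean 2.5, sd 0.645497,
        # z = (3 - 2.5)/0.645497
        trait = pd.Series([1.0, 2.0, 3.0, 4.0], index=["a", "b", "c", "d"])
        mem = DonorMembership("c", {"b", "d"}, {"a", "b", "c", "d"})
        res = quantitative_enrichment(mem, trait, n_perm=10_000, seed=0)
        assert res.statistic == pytest.approx(0.774597, abs=1e-6)
        assert res.n_perm == 6  # exhaustive path

    def test_entire_cohort_membership_degenerate_zero_z(self):
        trait = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        mem = DonorMembership("c", {"a", "b", "c"}, {"a", "b", "c"})
        res = quantitative_enrichment(mem, trait)
        assert res.degenerate and res.statistic == 0.0 and res.p == 1.0

    def test_z_grows_with_planted_shift(self, rng):
        cohort = [f"d{i}" for i in range(80)]
        base = pd.Series(rng.normal(size=80), index=cohort)
        members = set(rng.choice(cohort, 15, replace=False))
        zs = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            trait = base.copy()
            trait[list(members)] += delta
            res = quantitative_enrichment(
                DonorMembership("c", members, set(cohort)), trait,
                n_perm=3000, seed=1)
            zs.append(res.statistic)
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_sampled_path_approximates_exhaustive_null(self):
        # on a cohort where both paths are available, the z statistics agree
        rng = np.random.default_rng(5)
        cohort = [f"d{i}" for i in range(12)]
        trait = pd.Series(rng.normal(size=12), index=cohort)
        members = set(cohort[:4])
        mem = DonorMembership("c", members, set(cohort))
        exact = quantitative_enrichment(mem, trait, n_perm=10_000, seed=0)  # C(12,4)=495
        sampled = quantitative_enrichment(mem, trait, n_perm=400, seed=0)
        assert exact.n_perm == 495
        assert sampled.statistic == pytest.approx(exact.statistic, abs=0.15)

    def test_too_few_members_rejected(self):
        trait = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            quantitative_enrichment(DonorMembership("c", {"a"}, {"a", "b", "c"}), trait)


class TestSetOverlap:
    def test_identical_sets_maximal_or_tiny_p(self):
        bg = {f"g{i}" for i in range(100)}
        A = {f"g{i}" for i in range(10)}
        orr, p = set_overlap_enrichment(A, A, bg)
        assert orr > 100
        assert p < 1e-10

    def test_disjoint_covering_sets_or_below_one(self):
        bg = {f"g{i}" for i in range(40)}
        A = {f"g{i}" for i in range(20)}
        orr, p = set_overlap_enrichment(A, bg - A, bg)
        assert orr < 1

    def test_random_sets_match_enumeration_oracle(self, rng):
        bg = [f"g{i}" for i in range(50)]
        A = set(rng.choice(bg, 12, replace=False))
        B = set(rng.choice(bg, 18, replace=False))
        orr, p = set_overlap_enrichment(A, B, bg)
        a = len(A & B)
        assert p == pytest.approx(
            fisher_oracle_two_sided(a, len(A) - a, len(B) - a, 50 - len(A | B) + 0),
            abs=1e-9,
        )

    def test_background_must_contain_sets(self):
        with pytest.raises(ValueError):
            set_overlap_enrichment({"x"}, {"y"}, {"y"})


class TestMeasurementWindow:
    def test_closest_to_death_within_window_selected(self):
        series = pd.DataFrame({
            "donor": ["d1"] * 3,
            "value": [10.0, 20.0, 30.0],
            "days_before_death": [200, 800, 1200],
        })
        out = last_measurement_before_death(series)
        assert out.loc["d1"] == 10.0

    def test_donor_with_no_qualifying_measurement_missing(self):
        series = pd.DataFrame({
            "donor": ["d1", "d2"],
            "value": [5.0, 7.0],
            "days_before_death": [2000, 100],
        })
        out = last_measurement_before_death(series)
        assert "d1" not in out.index and out.loc["d2"] == 7.0

    def test_exact_three_year_boundary_inclusive(self):
        series = pd.DataFrame({
            "donor": ["d1"], "value": [9.0], "days_before_death": [1095],
        })
        out = last_measurement_before_death(series)
        assert out.loc["d1"] == 9.0

    def test_negative_times_rejected(self):
        series = pd.DataFrame({"donor": ["d"], "value": [1.0],
                               "days_before_death": [-1]})
        with pytest.raises(ValueError):
            last_measurement_before_death(series)


class TestGenotypeTraitAssoc:
    def test_noise_free_slope_exact(self):
        dose = np.tile([0.0, 1.0, 2.0], 5)
        out = genotype_trait_assoc(dose, 2.0 * dose)
        assert out["beta"] == pytest.approx(2.0, abs=1e-10)

    def test_interaction_recovers_opposite_sign_strata(self):
        from cellink.synth import SimConfig, sim_donor_traits, sim_genotypes

        geno = sim_genotypes(SimConfig(n_donors=2000, n_variants=3, seed=31))
        dt = sim_donor_traits(geno, main_beta=0.6, interaction_beta=-0.3,
                              pathology_model="quantitative", noise_sd=0.5, seed=2)
        df = dt.donors
        out = genotype_trait_assoc(
            df["dosage"].to_numpy(), df["trait"].to_numpy(),
            covariates=df[["age", "sex", "education"]],
            interaction=df["pathology"].to_numpy(), log_transform=False,
        )
        assert out["beta_int"] == pytest.approx(-0.3, abs=0.05)
        assert out["p_int"] < 1e-10

    def test_log_transform_applied_to_pathology(self, rng):
        dose = rng.integers(0, 3, 200).astype(float)
        path = rng.gamma(2, 2, 200)
        trait = 0.5 * dose * np.log1p(path) + rng.normal(0, 0.2, 200)
        out = genotype_trait_assoc(dose, trait, interaction=path, log_transform=True)
        assert out["beta_int"] == pytest.approx(0.5, abs=0.1)

    def test_permuted_dosage_p_uniform(self, rng):
        trait = rng.normal(size=80)
        ps = []
        for _ in range(300):
            dose = rng.permutation(np.tile([0.0, 1.0, 2.0], 27)[:80])
            ps.append(genotype_trait_assoc(dose, trait)["p"])
        ps = np.array(ps)
        assert abs((ps < 0.05).mean() - 0.05) < 0.04
        assert abs(np.mean(ps) - 0.5) < 0.06

    def test_singular_design_reports_collinear_columns(self):
        dose = np.tile([0.0, 1.0, 2.0], 5)
        cov = pd.DataFrame({"twice_dosage": 2 * dose})
        with pytest.raises(ValueError, match="collinear"):
            genotype_trait_assoc(dose, np.ones(15), covariates=cov)

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            genotype_trait_assoc(np.ones(20), np.arange(20.0))


class TestDetectionShare:
    def test_share_is_percentage(self):
        assert detection_share(1, 4) == 25.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            detection_share(5, 4)
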