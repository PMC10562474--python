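"""Generative engine: LD-derived mixture proportions, count scaffolding,
parameter draws, and the three per-gene generators."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from daesc.simulate import (ParamDraw, SimScenario, draw_params,
                            generate_totals, haplotype_mixture_probs,
                            load_scenario, scenario_grid, simulate_dataset,
                            simulate_glmm_gene, simulate_multi_eqtl,
                            simulate_one_eqtl)


def _enumeration_probs(pA, pB, r2):
    """Independent oracle: enumerate haplotype pairs explicitly."""
    D = np.sqrt(r2 * pA * (1 - pA) * pB * (1 - pB))
    h = {(1, 1): pA * pB + D, (1, 0): pA * (1 - pB) - D,
         (0, 1): (1 - pA) * pB - D, (0, 0): (1 - pA) * (1 - pB) + D}
    num = {-1: 0.0, 1: 0.0, 0: 0.0}
    den = 0.0
    for alt_hap, ref_hap in itertools.product([0, 1], repeat=2):
        # first haplotype carries the tSNP alt allele, second the ref
        p = h[(alt_hap, 1)] * h[(ref_hap, 0)]
        den += p
        if alt_hap == 1 and ref_hap == 0:
            num[1] += p
        elif alt_hap == 0 and ref_hap == 1:
            num[-1] += p
        else:
            num[0] += p
    return num[-1] / den, num[1] / den, num[0] / den


class TestHaplotypeMixtureProbs:
    def test_independent_loci_half_frequency(self):
        p = haplotype_mixture_probs(0.5, 0.5, 0.0)
        assert (p.pi1, p.pi2, p.pi3) == pytest.approx((0.25, 0.25, 0.5))

    def test_perfect_positive_ld(self):
        p = haplotype_mixture_probs(0.2, 0.2, 1.0)
        assert p.pi2 == pytest.approx(1.0, abs=1e-12)
        assert p.pi1 == pytest.approx(0.0, abs=1e-12)
        assert p.pi3 == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        p = haplotype_mixture_probs(0.3, 0.3, 0.1)
        want = _enumeration_probs(0.3, 0.3, 0.1)
        assert (p.pi1, p.pi2, p.pi3) == pytest.approx(want, abs=1e-12)

    def test_inadmissible_combination_names_bound(self):
        # r2=1 with unequal frequencies forces a negative haplotype freq
        with pytest.raises(ValueError, match="haplotype frequency"):
            haplotype_mixture_probs(0.05, 0.5, 1.0)

    @given(pA=st.floats(0.05, 0.5), pB=st.floats(0.05, 0.5),
           r2=st.floats(0.0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_when_admissible(self, pA, pB, r2):
        try:
            p = haplotype_mixture_probs(pA, pB, r2)
        except ValueError:
            return
        assert p.pi1 + p.pi2 + p.pi3 == pytest.approx(1.0, abs=1e-12)
        assert min(p.pi1, p.pi2, p.pi3) >= 0


class TestGenerateTotals:
    def test_mean_and_positivity(self):
        sc = SimScenario(n_donors=50, cells_per_donor=(20, 2.0),
                         depth=(20, 0.8), seed=1)
        totals, donor_index = generate_totals(sc)
        assert totals.min() >= 1
        assert abs(totals.mean() - 20) / 20 < 0.10
        assert len(totals) == len(donor_index)

    def test_seed_reproducibility(self):
        sc = SimScenario(n_donors=10, cells_per_donor=(15, 2.0), seed=7)
        t1, d1 = generate_totals(sc)
        t2, d2 = generate_totals(sc)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(d1, d2)

    def test_explicit_cell_counts(self):
        sc = SimScenario(n_donors=4, cells_per_donor=(3, 5, 2, 4), seed=0)
        totals, donor_index = generate_totals(sc)
        np.testing.assert_array_equal(np.bincount(donor_index), [3, 5, 2, 4])


class TestDrawParams:
    def test_null_resets_beta1(self):
        draw = draw_params(None, np.random.default_rng(0), null=True)
        assert draw.beta1 == 0.0

    def test_library_row_returned_unchanged(self):
        lib = pd.DataFrame([{"beta0": 0.2, "beta1": -1.1,
                             "sigma2_a": 0.4, "phi": 0.1}])
        draw = draw_params(lib, np.random.default_rng(3))
        assert draw == ParamDraw(0.2, -1.1, 0.4, 0.1)

    def test_uniform_over_library_rows(self):
        lib = pd.DataFrame({"beta0": [0.1, 0.2, 0.3], "beta1": [1, 2, 3],
                            "sigma2_a": [0.1] * 3, "phi": [0.1] * 3})
        rng = np.random.default_rng(11)
        draws = [draw_params(lib, rng).beta1 for _ in range(3000)]
        counts = pd.Series(draws).value_counts()
        se = np.sqrt(3000 * (1 / 3) * (2 / 3))
        for c in counts:
            assert abs(c - 1000) < 3 * se

    def test_malformed_library_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            draw_params(pd.DataFrame({"beta0": [1.0]}),
                        np.random.default_rng(0))


class TestOneEqtlGenerator:
    def test_null_flag_follows_beta1(self):
        sc = SimScenario(n_donors=10, cells_per_donor=(6, 2.0), seed=3)
        g = simulate_one_eqtl(sc, ParamDraw(0.5, 0.0, 0.2, 0.1))
        assert g.is_null and g.beta1_true == 0.0

    def test_z_frequencies_match_mixture_probs(self):
        sc = SimScenario(n_donors=300, cells_per_donor=(2, 2.0),
                         r2=0.0, maf_eqtl=0.3, maf_tsnp=0.3, seed=5)
        g = simulate_one_eqtl(sc, ParamDraw(0.5, 1.0, 0.2, 0.1))
        probs = sc.mixture_probs()
        obs = [np.sum(g.z_true == v) for v in (-1, 1, 0)]
        expected = np.array([probs.pi1, probs.pi2, probs.pi3]) * 300
        assert stats.chisquare(obs, expected).pvalue > 0.01

    def test_overdispersion_recovered_by_pooled_fit(self):
        """Pooled fixed-effects fits on many genes with phi=0.2 should
        average back near 0.2."""
        from daesc.betabin import fit_betabin_fixed
        phis = []
        rng = np.random.default_rng(6)
        for k in range(25):
            sc = SimScenario(n_donors=2, cells_per_donor=(150, 5.0),
                             depth=(20, 0.8), r2=1.0, maf_eqtl=0.5,
                             maf_tsnp=0.5, seed=600 + k, eta_effect=False)
            g = simulate_one_eqtl(sc, ParamDraw(0.4, 0.8, 1e-12, 0.2), rng)
            phis.append(fit_betabin_fixed(g.data).phi)
        assert 0.15 <= np.mean(phis) <= 0.25

    def test_seed_reproducibility(self):
        sc = SimScenario(n_donors=8, cells_per_donor=(6, 2.0), seed=9)
        g1 = simulate_one_eqtl(sc, ParamDraw(0.5, 1.0, 0.2, 0.1))
        g2 = simulate_one_eqtl(sc, ParamDraw(0.5, 1.0, 0.2, 0.1))
        np.testing.assert_array_equal(g1.data.y, g2.data.y)
        np.testing.assert_array_equal(g1.z_true, g2.z_true)

    def test_explicit_z_override(self):
        sc = SimScenario(n_donors=6, cells_per_donor=(5, 2.0), seed=2)
        z = np.array([1, 1, 1, -1, -1, -1])
        g = simulate_one_eqtl(sc, ParamDraw(1.0, 1.0, 0.1, 0.1), z=z)
        np.testing.assert_array_equal(g.z_true, z)


class TestGlmmGenerator:
    def test_cell_effect_variance_is_one(self):
        """At very high depth the empirical logit isolates the cell-level
        Gaussian effect, whose variance is fixed at 1."""
        sc = SimScenario(n_donors=40, cells_per_donor=(500, 5.0),
                         depth=(800, 5.0), r2=1.0, maf_eqtl=0.5,
                         maf_tsnp=0.5, seed=12, eta_effect=False)
        g = simulate_glmm_gene(sc, ParamDraw(0.0, 0.0, 1e-12, 0.01))
        lo = np.log((g.data.y + 0.5) / (g.data.n - g.data.y + 0.5))
        assert 0.9 <= np.var(lo) <= 1.1

    def test_z_frequency_contract_shared_with_betabin(self):
        sc = SimScenario(n_donors=300, cells_per_donor=(2, 2.0), r2=0.1,
                         maf_eqtl=0.25, maf_tsnp=0.25, seed=13)
        g = simulate_glmm_gene(sc, ParamDraw(0.5, 1.0, 0.2, 0.01))
        probs = sc.mixture_probs()
        obs = [np.sum(g.z_true == v) for v in (-1, 1, 0)]
        expected = np.array([probs.pi1, probs.pi2, probs.pi3]) * 300
        assert stats.chisquare(obs, expected).pvalue > 0.01

    def test_seed_reproducibility(self):
        sc = SimScenario(n_donors=8, cells_per_donor=(6, 2.0), seed=14)
        g1 = simulate_glmm_gene(sc, ParamDraw(0.5, 1.0, 0.2, 0.01))
        g2 = simulate_glmm_gene(sc, ParamDraw(0.5, 1.0, 0.2, 0.01))
        np.testing.assert_array_equal(g1.data.y, g2.data.y)


class TestMultiEqtlGenerator:
    def test_effective_coefficients_are_hand_sums(self):
        sc = SimScenario(n_donors=30, cells_per_donor=(5, 2.0), m_eqtls=3,
                         seed=21)
        g = simulate_multi_eqtl(sc)
        diff = g.g1 - g.g0
        np.testing.assert_allclose(g.beta_ase0, diff @ g.beta_k0,
                                   atol=1e-12)
        np.testing.assert_allclose(g.beta_ase1, diff @ g.beta_k1,
                                   atol=1e-12)

    def test_matched_haplotypes_cancel(self):
        sc = SimScenario(n_donors=200, cells_per_donor=(2, 2.0), m_eqtls=2,
                         seed=22)
        g = simulate_multi_eqtl(sc)
        same = np.all(g.g1 == g.g0, axis=1)
        assert same.any()  # matched donors occur at these frequencies
        np.testing.assert_array_equal(g.beta_ase1[same], 0.0)
        np.testing.assert_array_equal(g.beta_ase0[same], 0.0)

    def test_many_distinct_effect_values_at_m6(self):
        sc = SimScenario(n_donors=200, cells_per_donor=(2, 2.0), m_eqtls=6,
                         seed=23)
        g = simulate_multi_eqtl(sc)
        assert len(np.unique(np.round(g.beta_ase1, 10))) > 2

    def test_null_genes_have_zero_effect(self):
        sc = SimScenario(n_donors=20, cells_per_donor=(4, 2.0), m_eqtls=3,
                         seed=24)
        g = simulate_multi_eqtl(sc, null=True)
        assert g.is_null
        np.testing.assert_array_equal(g.beta_ase1, 0.0)

    def test_requires_two_eqtls(self):
        sc = SimScenario(n_donors=10, cells_per_donor=(4, 2.0), m_eqtls=1,
                         seed=25)
        with pytest.raises(ValueError):
            simulate_multi_eqtl(sc)


class TestDatasetAndScenarios:
    def test_dataset_shapes_and_truth(self):
        sc = SimScenario(n_donors=6, cells_per_donor=(4, 2.0), n_null=3,
                         n_alt=2, seed=31)
        counts, truth, genes = simulate_dataset(sc)
        assert truth["gene"].nunique() == 5
        assert counts["gene"].nunique() == 5
        per_gene = truth.groupby("gene")["is_null"].first()
        assert per_gene.sum() == 3

    def test_odd_donor_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            SimScenario(n_donors=7)

    def test_binary_covariate_is_donor_constant(self):
        sc = SimScenario(n_donors=6, cells_per_donor=(5, 2.0),
                         covariate="binary", seed=33)
        g = simulate_one_eqtl(sc, ParamDraw(0.5, 1.0, 0.2, 0.1))
        df = g.data.to_dataframe()
        assert (df.groupby("donor")["x"].nunique() == 1).all()
        assert set(df["x"].unique()) == {0.0, 1.0}
        assert df.groupby("donor")["x"].first().sum() == 3  # N/2 cases

    def test_grid_shape(self):
        grid = scenario_grid(n_null=5, n_alt=5,
                             cells_per_donor=(10, 2.0))
        assert len(grid) == 9
        assert {s.r2 for s in grid} == {0.0, 0.1, 0.9}
        assert {s.n_donors for s in grid} == {10, 50, 100}

    def test_scenario_file_round_trip(self, tmp_path):
        path = tmp_path / "s.cfg"
        path.write_text("n_donors = 12\nr2 = 0.1\nn_null = 4\nn_alt = 2\n"
                        "cells_per_donor = 8, 2.0\ndepth = 12, 0.8\n"
                        "covariate = continuous\nseed = 5\n# comment\n")
        sc = load_scenario(path)
        assert sc.n_donors == 12 and sc.r2 == 0.1
        assert sc.cells_per_donor == (8.0, 2.0)

    def test_unknown_scenario_key_rejected(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("n_donor = 12\n")
        with pytest.raises(ValueError, match="unknown scenario keys"):
            load_scenario(path)
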