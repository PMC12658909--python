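"""Estimator correctness: frequencies, heterozygosity, rarefaction,
Weir–Cockerham components against a hand-evaluated oracle, permutation
significance, LD-Ne and DAPC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seascapegen import popgen
from seascapegen.genotypes import MISSING
from seascapegen.simulate import (PopSpec, simulate_ancestral_frequencies,
                                  simulate_genotypes)
from conftest import make_matrix


class TestAlleleFrequencies:
    def test_basic_and_missing_handling(self):
        G = make_matrix([[0, MISSING], [1, MISSING], [2, MISSING]], ["A"] * 3)
        f = popgen.allele_frequencies(G)
        assert f.loc["L1", "A"] == 0.5
        assert np.isnan(f.loc["L2", "A"])  # all-missing cell is undefined, not 0

    def test_two_allele_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        G = make_matrix(rng.integers(0, 3, size=(30, 6)), ["A"] * 15 + ["B"] * 15)
        f = popgen.allele_frequencies(G)
        assert np.allclose(f + (1 - f), 1.0)


class TestHeterozygosities:
    def test_all_heterozygotes(self):
        G = make_matrix(np.ones((10, 3), int), ["A"] * 10)
        summary, _ = popgen.heterozygosities(G)
        assert summary["Ho"].iloc[0] == 1.0

    def test_unbiased_he_closed_form(self):
        # p = 0.5, n = 10: He = 0.5 * 20/19 = 0.526315...
        calls = np.array([[0]] * 5 + [[2]] * 5)
        G = make_matrix(calls, ["A"] * 10)
        _, detail = popgen.heterozygosities(G)
        assert detail["He"].iloc[0] == pytest.approx(0.5 * 20 / 19, abs=1e-12)

    def test_monomorphic_locus_zero(self):
        G = make_matrix(np.zeros((8, 1), int), ["A"] * 8)
        summary, _ = popgen.heterozygosities(G)
        assert summary["Ho"].iloc[0] == 0.0
        assert summary["He"].iloc[0] == 0.0

    def test_unbiased_he_never_below_plugin(self):
        rng = np.random.default_rng(1)
        G = make_matrix(rng.integers(0, 3, size=(12, 10)), ["A"] * 12)
        _, detail = popgen.heterozygosities(G)
        f = popgen.allele_frequencies(G)["A"].to_numpy()
        plugin = 2 * f * (1 - f)
        assert (detail["He"].to_numpy() >= plugin - 1e-12).all()


class TestAllelicRichness:
    def test_full_sample_counts_alleles(self):
        G = make_matrix([[0], [1], [2], [2]], ["A"] * 4)
        ar = popgen.allelic_richness(G, g=8)
        assert ar["Ar"].iloc[0] == pytest.approx(2.0)

    def test_combinatorial_arithmetic(self):
        # allele counts (19, 1) in 2N=20 copies, g=2:
        # Ar = 2 - C(1,2)/C(20,2) - C(19,2)/C(20,2) = 2 - 0 - 171/190 = 1.1
        calls = np.zeros((10, 1), dtype=np.int16)
        calls[0, 0] = 1
        G = make_matrix(calls, ["A"] * 10)
        ar = popgen.allelic_richness(G, g=2)
        assert ar["Ar"].iloc[0] == pytest.approx(1.1, abs=1e-12)

    def test_monomorphic_is_one_at_any_g(self):
        G = make_matrix(np.full((6, 1), 2), ["A"] * 6)
        for g in (2, 5, 12):
            assert popgen.allelic_richness(G, g=g)["Ar"].iloc[0] == pytest.approx(1.0)

    def test_monotone_in_g(self):
        rng = np.random.default_rng(2)
        G = make_matrix(rng.integers(0, 3, size=(15, 8)), ["A"] * 15)
        values = [popgen.allelic_richness(G, g=g)["Ar"].iloc[0]
                  for g in range(2, 30, 4)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_g_exceeding_minimum_copies_rejected(self):
        G = make_matrix([[0], [1]], ["A", "B"])  # 2 copies per pop
        with pytest.raises(ValueError, match="exceeds"):
            popgen.allelic_richness(G, g=4)


def wc_oracle_two_pops(geno_a, geno_b):
    """Independent hand-transcription of the W&C (1984) single-locus
    variance components for two samples of diploids (complete data)."""
    def moments(g):
        g = np.asarray(g, float)
        return len(g), g.sum() / (2 * len(g)), np.mean(g == 1)

    n1, p1, h1 = moments(geno_a)
    n2, p2, h2 = moments(geno_b)
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWeirCockerham:
    def test_components_match_hand_oracle_to_1e12(self):
        geno_a = [0, 1, 1, 2, 2]
        geno_b = [0, 0, 1, 2]
        a, b, c = wc_oracle_two_pops(geno_a, geno_b)
        G = make_matrix([[g] for g in geno_a + geno_b], ["A"] * 5 + ["B"] * 4)
        comp = popgen.weir_cockerham_components(G)
        assert comp["a"].iloc[0] == pytest.approx(a, abs=1e-12)
        assert comp["b"].iloc[0] == pytest.approx(b, abs=1e-12)
        assert comp["c"].iloc[0] == pytest.approx(c, abs=1e-12)
        theta = popgen.pairwise_fst(G).theta.loc["A", "B"]
        assert theta == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_theta_one_for_opposite_fixed(self, opposite_fixed):
        theta = popgen.pairwise_fst(opposite_fixed).theta.loc["A", "B"]
        assert theta == pytest.approx(1.0, abs=1e-12)

    def test_theta_near_zero_for_identical_frequencies(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(400, 30))
        G = make_matrix(calls, ["A"] * 200 + ["B"] * 200)
        theta = popgen.pairwise_fst(G).theta.loc["A", "B"]
        assert abs(theta) < 0.01

    def test_invariance_to_allele_swap_and_pop_order(self, diverged_pair):
        G, _, _ = diverged_pair
        t1 = popgen.pairwise_fst(G).theta.loc["A", "B"]
        swapped = make_matrix(2 - G.calls, list(G.population_labels))
        t2 = popgen.pairwise_fst(swapped).theta.loc["A", "B"]
        assert t1 == pytest.approx(t2, abs=1e-12)
        order = np.argsort(G.population_labels != "B", kind="stable")
        reordered = G.subset_individuals(order)
        t3 = popgen.pairwise_fst(reordered).theta.loc["B", "A"]
        assert t1 == pytest.approx(t3, abs=1e-12)


class TestFis:
    def test_all_heterozygotes_gives_minus_one(self):
        G = make_matrix(np.ones((12, 2), int), ["A"] * 6 + ["B"] * 6)
        fis = popgen.fis_weir_cockerham(G, "locus_across_populations")
        assert np.allclose(fis["Fis"], -1.0)

    def test_wahlund_pool_gives_plus_one(self):
        calls = np.vstack([np.zeros((10, 2)), np.full((10, 2), 2)])
        G = make_matrix(calls, ["A"] * 20)
        fis = popgen.fis_weir_cockerham(G, "per_population")
        assert fis["Fis"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_hw_population_near_zero(self):
        freqs = simulate_ancestral_frequencies(100, 0.3, seed=4)
        G, _ = simulate_genotypes(freqs, [PopSpec("A", 500, 1.0, 0.0)], seed=5)
        fis = popgen.fis_weir_cockerham(G, "per_population")
        assert abs(fis["Fis"].iloc[0]) < 0.05

    def test_three_scopes_have_expected_shapes(self, diverged_pair):
        G, _, _ = diverged_pair
        across = popgen.fis_weir_cockerham(G, "locus_across_populations")
        within = popgen.fis_weir_cockerham(G, "locus_within_population")
        per_pop = popgen.fis_weir_cockerham(G, "per_population")
        assert len(across) == G.n_loci
        assert len(within) == G.n_loci * 2
        assert len(per_pop) == 2


class TestPermutationSignificance:
    def test_opposite_fixed_minimal_p(self, opposite_fixed):
        res = popgen.fst_significance(opposite_fixed, 1000, seed=1)
        assert res.p_values.loc["A", "B"] == pytest.approx(1 / 1001)

    def test_seeded_repeat_identical(self, tiny_two_pop):
        a = popgen.fst_significance(tiny_two_pop, 50, seed=3).p_values
        b = popgen.fst_significance(tiny_two_pop, 50, seed=3).p_values
        assert a.equals(b)

    def test_invalid_permutation_count(self, tiny_two_pop):
        with pytest.raises(ValueError):
            popgen.fst_significance(tiny_two_pop, 0, seed=1)

    def test_null_calibration_uniform(self):
        # two samples from one panmictic pool: p-values ~ Uniform(0,1)
        rng = np.random.default_rng(7)
        pvals = []
        for rep in range(200):
            calls = rng.choice([0, 1, 2], p=[0.36, 0.48, 0.16], size=(40, 25))
            G = make_matrix(calls, ["A"] * 20 + ["B"] * 20)
            res = popgen.fst_significance(G, 99, seed=int(rng.integers(2**31)))
            pvals.append(res.p_values.loc["A", "B"])
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.001


class TestBonferroni:
    @pytest.mark.parametrize("n,alpha,expected", [
        (26, 0.05, 0.05 / 325),
        (2, 0.05, 0.05),
        (10, 0.05, 0.05 / 45),
    ])
    def test_threshold(self, n, alpha, expected):
        assert popgen.bonferroni_threshold(n, alpha) == pytest.approx(expected)

    def test_three_sig_figs_reporting(self):
        assert popgen.round_sig(popgen.bonferroni_threshold(26), 3) == 0.000154


class TestLdNe:
    def test_mixture_ld_shrinks_ne(self):
        freqs = simulate_ancestral_frequencies(120, 0.5, seed=6)
        G, _ = simulate_genotypes(
            freqs, [PopSpec("A", 60, 1.0), PopSpec("B", 60, 0.0)], seed=7)
        pure = popgen.ld_ne(G, seed=1)
        mixed = make_matrix(G.calls, ["M"] * 120)
        mix = popgen.ld_ne(mixed, seed=1)[0]
        assert np.isfinite(mix.ne)
        assert mix.ne < min(e.ne for e in pure)

    def test_infinite_representation_and_log10_substitute(self):
        # independent binomial draws carry no drift LD: Ne is INFINITE
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, 0.5, size=(200, 60))
        G = make_matrix(calls, ["A"] * 200)
        est = popgen.ld_ne(G, seed=2)[0]
        assert np.isinf(est.ne) or est.ne > 1000
        if np.isinf(est.ne):
            assert est.ne_for_log10() == 1000.0

    def test_too_few_loci_is_an_error(self):
        G = make_matrix([[0], [1], [2]], ["A"] * 3)
        with pytest.raises(ValueError, match="usable loci"):
            popgen.ld_ne(G)


class TestDapc:
    def test_separated_lineages_load_on_axis_one(self):
        freqs = simulate_ancestral_frequencies(200, 0.5, seed=9)
        G, _ = simulate_genotypes(
            freqs, [PopSpec("A", 60, 1.0), PopSpec("B", 60, 0.0),
                    PopSpec("C", 60, 0.5)], seed=10)
        res = popgen.dapc(G, n_pcs=30)
        assert res.var_pct[0] > 95.0
        axes = [c for c in res.coords.columns if c.startswith("LD")]
        within_sd = res.coords.groupby("group")[axes[0]].std().mean()
        sep = abs(res.centroids.loc["A", axes[0]] - res.centroids.loc["B", axes[0]])
        assert sep > 5 * within_sd

    def test_identical_groups_not_separable(self):
        rng = np.random.default_rng(11)
        calls = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(80, 40))
        labels = ["A"] * 40 + ["B"] * 40  # arbitrary split of one pool
        G = make_matrix(calls, labels)
        res = popgen.dapc(G, n_pcs=20)
        obs = abs(res.centroids.iloc[0, 0] - res.centroids.iloc[1, 0])
        null = []
        for _ in range(99):
            perm = rng.permutation(80)
            res_p = popgen.dapc(G.subset_individuals(perm),
                                group_labels=np.asarray(labels), n_pcs=20)
            null.append(abs(res_p.centroids.iloc[0, 0] - res_p.centroids.iloc[1, 0]))
        assert obs <= np.quantile(null, 0.99)

    def test_axis_count_validation(self, tiny_two_pop):
        with pytest.raises(ValueError, match="n_axes"):
            popgen.dapc(tiny_two_pop, n_pcs=2, n_axes=5)

    def test_variance_percentages_bounded(self, diverged_pair):
        G, _, _ = diverged_pair
        res = popgen.dapc(G, n_pcs=20)
        assert (res.var_pct >= 0).all() and res.var_pct.sum() <= 100.0 + 1e-9


def test_diversity_table_assembles_all_columns(diverged_pair):
    G, _, _ = diverged_pair
    tbl = popgen.diversity_table(G)
    assert set(tbl.columns) >= {"population", "N", "Ho", "He", "Ar", "Fis",
                                "Ne", "Ne_ci_low", "Ne_ci_high"}
    assert ((tbl["Ho"] >= 0) & (tbl["Ho"] <= 1)).all()
    assert ((tbl["Ar"] >= 1) & (tbl["Ar"] <= 2)).all()
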