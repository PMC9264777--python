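"""SNP-effect back-solving, nonlinear weights, the weighted iteration loop."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from ssgblup.grm import GenomicMatrix, HInverseParams, blend_G, build_G
from ssgblup.mme import ModelSpec, VarianceComponents
from ssgblup.pedigree import build_A, subset_A22
from ssgblup.qc import GenotypeMatrix
from ssgblup.wssgblup import (WeightingError, backsolve_snp_effects,
                              nonlinearA_weights, normalize_weights,
                              run_ssgblup, run_wssgblup, snp_set_overlap,
                              top_snp_set, variance_explained)


def random_genotypes(rng, n, m) -> GenotypeMatrix:
    freqs = rng.uniform(0.1, 0.9, m)
    dos = (rng.random((n, m)) < freqs).astype(float) + (rng.random((n, m)) < freqs)
    return GenotypeMatrix(dos, [f"g{i}" for i in range(n)], [f"s{j}" for j in range(m)])


class TestBacksolve:
    def test_zero_gebv_gives_zero_effects(self):
        rng = np.random.default_rng(0)
        gm = random_genotypes(rng, 30, 80)
        G = build_G(gm)
        eff = backsolve_snp_effects(gm, np.ones(80), G, np.zeros(30))
        assert np.abs(eff.a_hat).max() == 0.0

    def test_one_snp_toy_solved_by_hand(self):
        # M = [-1, 0, 1], k = 0.5, u = [2, 0, -2] = -2*M  =>  a_hat = -2
        gm = GenotypeMatrix(np.array([[0.0], [1.0], [2.0]]), ["a", "b", "c"], ["s1"])
        G = build_G(gm)
        u = np.array([2.0, 0.0, -2.0])
        eff = backsolve_snp_effects(gm, np.ones(1), G, u)
        assert eff.a_hat[0] == pytest.approx(-2.0, abs=1e-10)
        M = gm.centered()
        assert np.abs(M @ eff.a_hat - u).max() < 1e-10

    def test_identity_with_unblended_weighted_G(self):
        """M a_hat = u_g exactly when G* was built from this M, D, k.

        Centering puts the ones vector in G's null space, so the identity is
        defined for GEBV vectors in range(G); real GEBV enter it up to their
        mean.
        """
        rng = np.random.default_rng(1)
        gm = random_genotypes(rng, 200, 500)
        d = rng.uniform(0.3, 2.5, 500)
        G = build_G(gm, weights=d)
        u_g = G.values @ rng.standard_normal(200)  # in range(G) by construction
        eff = backsolve_snp_effects(gm, d, G, u_g)
        M = gm.centered()
        assert np.abs(M @ eff.a_hat - u_g).max() < 1e-6

    def test_gebv_outside_range_of_singular_G_raises(self):
        gm = GenotypeMatrix(np.array([[0.0], [1.0], [2.0]]), ["a", "b", "c"], ["s1"])
        G = build_G(gm)  # rank 1
        with pytest.raises(WeightingError, match="range"):
            backsolve_snp_effects(gm, np.ones(1), G, np.array([1.0, 1.0, 1.0]))


class TestWeights:
    def test_two_and_three_sd_and_zero_exact(self):
        # [2,-2,3,-3] padded with 22 zeros has population sd exactly 1,
        # so entries sit at exactly 2 sd, 3 sd and 0 sd
        a = np.array([2.0, -2.0, 3.0, -3.0] + [0.0] * 22)
        assert np.std(a) == pytest.approx(1.0, abs=1e-14)
        d = nonlinearA_weights(a)
        assert d[0] == pytest.approx(1.0, abs=1e-12)          # |a| = 2 sd
        assert d[2] == pytest.approx(1.125, abs=1e-12)        # |a| = 3 sd
        assert d[4] == pytest.approx(1.125 ** -2, abs=1e-12)  # a = 0, ~0.7901

    def test_formula_shape(self):
        a = np.array([0.0, 1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        sd = float(np.std(a))
        d = nonlinearA_weights(a)
        assert np.allclose(d, 1.125 ** (np.abs(a) / sd - 2.0))

    def test_exponent_cap(self):
        a = np.array([100.0] + [0.001] * 99)
        d = nonlinearA_weights(a)
        assert d.max() <= 1.125 ** 5 + 1e-12

    def test_constant_effects_raise(self):
        with pytest.raises(WeightingError, match="sd"):
            nonlinearA_weights(np.ones(10))

    def test_normalization_constraint(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 50)
        het = 2 * p * (1 - p)
        d = rng.uniform(0.1, 5.0, 50)
        dn = normalize_weights(d, p)
        assert np.sum(dn * het) == pytest.approx(np.sum(het), abs=1e-10)

    def test_already_normalized_unchanged(self):
        p = np.full(4, 0.5)
        d = np.array([1.0, 1.0, 1.0, 1.0])
        assert np.allclose(normalize_weights(d, p), d)

    def test_constant_weights_become_one(self):
        p = np.array([0.1, 0.3, 0.5])
        assert np.allclose(normalize_weights(np.full(3, 7.3), p), 1.0)

    def test_zero_weights_raise(self):
        with pytest.raises(WeightingError, match="zero"):
            normalize_weights(np.zeros(3), np.full(3, 0.5))


class TestVarianceShares:
    def test_single_nonzero_effect(self):
        share = variance_explained(np.array([0.0, 2.0, 0.0]), np.full(3, 0.3))
        assert np.allclose(share, [0.0, 1.0, 0.0])

    def test_equal_effects_equal_freqs(self):
        share = variance_explained(np.ones(8), np.full(8, 0.2))
        assert np.allclose(share, 1.0 / 8.0)

    def test_hand_toy(self):
        share = variance_explained(np.array([1.0, 2.0]), np.array([0.5, 0.5]))
        assert np.allclose(share, [0.2, 0.8])

    def test_zero_denominator_raises(self):
        with pytest.raises(WeightingError):
            variance_explained(np.zeros(3), np.full(3, 0.5))


class TestTopSnpSet:
    def test_simple(self):
        assert top_snp_set(np.array([0.5, 0.3, 0.2]), 0.5) == [0]

    def test_uniform_shares(self):
        shares = np.full(1000, 1e-3)
        assert len(top_snp_set(shares, 0.05)) == 50

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            s = rng.dirichlet(np.ones(8))
            frac = float(rng.uniform(0.2, 0.9))
            k_sort = len(top_snp_set(s, frac))
            k_brute = next(k for k in range(1, 9)
                           if any(s[list(c)].sum() >= frac - 1e-12
                                  for c in combinations(range(8), k)))
            assert k_sort == k_brute

    def test_bad_fraction(self):
        with pytest.raises(WeightingError):
            top_snp_set(np.array([1.0]), 0.0)


class TestOverlap:
    def test_identical_sets(self):
        out = snp_set_overlap([{1, 2, 3}, {1, 2, 3}])
        assert out[(0, 1)] == 3 and out[(0,)] == 0 and out[(1,)] == 0

    def test_disjoint(self):
        out = snp_set_overlap([{1, 2}, {3}])
        assert out[(0, 1)] == 0 and out[(0,)] == 2 and out[(1,)] == 1

    def test_partial(self):
        out = snp_set_overlap([{1, 2, 3}, {2, 3, 4}])
        assert out[(0, 1)] == 2 and out[(0,)] == 1 and out[(1,)] == 1

    def test_three_sets_partition_sums(self):
        rng = np.random.default_rng(4)
        sets = [set(rng.choice(30, 12, replace=False)) for _ in range(3)]
        out = snp_set_overlap(sets)
        assert sum(out.values()) == len(set().union(*sets))


class TestIterationLoop:
    def test_iteration_one_is_ssgblup(self, small_population):
        pop = small_population
        vc = VarianceComponents(pop.sigma2_a, pop.sigma2_e)
        model = ModelSpec("trait", ("cg", "sex"))
        gm = pop.genotyped_matrix()
        ss = run_ssgblup(model, pop.phenotypes, pop.pedigree, gm, vc,
                         compute_pev=False)
        wss, _, trace = run_wssgblup(model, pop.phenotypes, pop.pedigree, gm, vc,
                                     n_iterations=1)
        assert np.abs(ss.u_hat.to_numpy() - wss.u_hat.to_numpy()).max() < 1e-10
        assert trace.records[0]["weight_min"] == trace.records[0]["weight_max"] == 1.0

    def test_normalization_holds_every_iteration(self, small_population):
        pop = small_population
        vc = VarianceComponents(pop.sigma2_a, pop.sigma2_e)
        gm = pop.genotyped_matrix()
        _, eff, trace = run_wssgblup(ModelSpec("trait", ("cg", "sex")),
                                     pop.phenotypes, pop.pedigree, gm, vc,
                                     n_iterations=3)
        p = gm.allele_frequencies()
        het = 2 * p * (1 - p)
        for d in trace.weights_by_iteration[1:] + [eff.weights]:
            assert np.sum(d * het) == pytest.approx(np.sum(het), abs=1e-8)

    def test_blended_backsolve_correlation(self, small_population):
        """With alpha=0.95 blending the identity M a = u_g holds approximately."""
        pop = small_population
        vc = VarianceComponents(pop.sigma2_a, pop.sigma2_e)
        gm = pop.genotyped_matrix()
        solve, eff, _ = run_wssgblup(ModelSpec("trait", ("cg", "sex")),
                                     pop.phenotypes, pop.pedigree, gm, vc,
                                     n_iterations=1)
        M = gm.centered()
        u_g = solve.u_hat.loc[gm.animal_ids].to_numpy()
        fitted = M @ eff.a_hat
        r = np.corrcoef(fitted, u_g)[0, 1]
        assert r > 0.99

    def test_qtl_enriched_in_top_share_set(self):
        """Designated QTL overrepresented among top-5%-variance SNPs
        (hypergeometric evidence combined over seeds)."""
        from ssgblup.simulate import SimulationConfig, simulate_population
        pvals = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                n_founders=150, n_generations=4, n_snps=400, n_qtl=10,
                heritability=0.5, qtl_effect_distribution="gamma-signed",
                genotyped_fraction_by_generation=[0, 0, 1.0, 1.0], seed=seed)
            pop = simulate_population(cfg)
            gm = pop.genotyped_matrix()
            vc = VarianceComponents(pop.sigma2_a, pop.sigma2_e)
            _, eff, _ = run_wssgblup(ModelSpec("trait", ("cg", "sex")),
                                     pop.phenotypes, pop.pedigree, gm, vc,
                                     n_iterations=2)
            top = set(top_snp_set(eff.variance_share, 0.05))
            qtl = set(int(j) for j in pop.qtl_indices)
            hits = len(top & qtl)
            pvals.append(stats.hypergeom.sf(hits - 1, gm.n_snps, len(qtl), len(top)))
        combined = stats.combine_pvalues(pvals, method="fisher").pvalue
        assert combined < 0.01
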