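"""Mixed-model equations: closed-form oracles, reliability, EM-REML."""

import numpy as np
import pandas as pd
import pytest

from ssgblup.grm import assemble_H_inverse
from ssgblup.mme import (ModelError, ModelSpec, TraitDataset, VarianceComponents,
                         assemble_mme, build_design, estimate_variance_components,
                         parent_average, run_animal_model, run_pedigree_blup,
                         solve_mme)
from ssgblup.pedigree import (Pedigree, RelationshipMatrix, UNKNOWN, build_A,
                              build_A_inverse)

from conftest import make_random_pedigree, unrelated_dataset

NO_FIXED = ModelSpec("trait", factors=(), intercept=False)


def founder_pedigree(n):
    return Pedigree([f"x{i}" for i in range(n)],
                    np.full(n, UNKNOWN, dtype=np.int64),
                    np.full(n, UNKNOWN, dtype=np.int64))


def dataset(ids, y, **cols):
    return TraitDataset(pd.DataFrame({"id": ids, "trait": y, **cols}))


class TestSolveClosedForms:
    def test_scalar_mme_lambda_one(self):
        # one animal, one record, no fixed effects: (1 + lambda) u = y
        ped = founder_pedigree(1)
        vc = VarianceComponents(1.0, 1.0)
        res = run_pedigree_blup(NO_FIXED, dataset(ped.ids, [3.0]), ped, vc)
        assert res.u_hat.iloc[0] == pytest.approx(1.5, abs=1e-12)

    def test_unrelated_shrinkage_is_h2(self):
        rng = np.random.default_rng(0)
        ped, data = unrelated_dataset(rng, 12)
        h2 = 0.35
        vc = VarianceComponents(h2, 1 - h2)  # phenotypic variance 1
        res = run_pedigree_blup(NO_FIXED, data, ped, vc)
        assert np.allclose(res.u_hat.to_numpy(),
                           h2 * data.data["trait"].to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_gls_blup_oracle(self, seed):
        """u = sigma2_a K Z'V^{-1}(y - Xb), b the GLS solution, V = ZKZ's_a + Is_e."""
        rng = np.random.default_rng(seed)
        ped = make_random_pedigree(rng, 50)
        n = ped.n
        df = pd.DataFrame({
            "id": ped.ids,
            "cg": rng.choice(["c1", "c2", "c3"], n),
            "sex": rng.choice(["M", "F"], n),
            "trait": rng.standard_normal(n) * 2.0 + 5.0,
        })
        data = TraitDataset(df)
        model = ModelSpec("trait", ("cg", "sex"))
        vc = VarianceComponents(0.4, 0.8)
        res = run_animal_model(model, data, ped, build_A_inverse(ped), vc)

        K = build_A(ped).dense()
        X, Z, y, _ = build_design(model, data, ped)
        Zd = Z.toarray()
        V = Zd @ K @ Zd.T * vc.sigma2_a + np.eye(n) * vc.sigma2_e
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = vc.sigma2_a * K @ Zd.T @ Vi @ (y - X @ b)
        assert np.abs(res.b_hat.to_numpy() - b).max() < 1e-6
        assert np.abs(res.u_hat.to_numpy() - u).max() < 1e-6


class TestReliability:
    def test_single_animal_reliability_equals_h2(self):
        for h2 in (0.112, 0.3, 0.428):
            ped = founder_pedigree(1)
            vc = VarianceComponents(h2, 1 - h2)
            res = run_pedigree_blup(NO_FIXED, dataset(ped.ids, [1.0]), ped, vc)
            assert res.reliability.iloc[0] == pytest.approx(h2, abs=1e-12)

    def test_animal_without_data_or_relatives(self):
        ped = founder_pedigree(2)
        data = dataset([ped.ids[0]], [2.0])
        vc = VarianceComponents(0.3, 0.7)
        res = run_pedigree_blup(NO_FIXED, data, ped, vc)
        assert res.u_hat.loc["x1"] == pytest.approx(0.0, abs=1e-14)
        assert res.reliability.loc["x1"] == pytest.approx(0.0, abs=1e-12)

    def test_reliability_in_unit_interval(self, small_population):
        pop = small_population
        vc = VarianceComponents(pop.sigma2_a, pop.sigma2_e)
        res = run_pedigree_blup(ModelSpec("trait", ("cg", "sex")),
                                pop.phenotypes, pop.pedigree, vc)
        r = res.reliability.to_numpy()
        assert (r >= 0.0).all() and (r <= 1.0).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_linking_phenotyped_relative_never_hurts(self, seed):
        """Information monotonicity: making a phenotyped animal a parent of
        the focal animal cannot decrease the focal animal's reliability."""
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(2)
        h2 = float(rng.uniform(0.1, 0.7))
        vc = VarianceComponents(h2, 1 - h2)
        unlinked = founder_pedigree(2)
        linked = Pedigree(["x0", "x1"], np.array([UNKNOWN, 0]),
                          np.array([UNKNOWN, UNKNOWN]))
        rel = {}
        for name, ped in (("unlinked", unlinked), ("linked", linked)):
            res = run_pedigree_blup(NO_FIXED, dataset(ped.ids, y), ped, vc)
            rel[name] = res.reliability.loc["x1"]
        assert rel["linked"] >= rel["unlinked"] - 1e-10


class TestStructure:
    def test_intercept_only_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        ped = make_random_pedigree(rng, 40)
        data = dataset(ped.ids, rng.standard_normal(40) + 3.0)
        model = ModelSpec("trait", factors=())
        vc = VarianceComponents(0.5, 0.5)
        system = assemble_mme(model, data, ped, build_A_inverse(ped), vc)
        res = solve_mme(system)
        resid = system.y - system.X @ res.b_hat.to_numpy() - system.Z @ res.u_hat.to_numpy()
        assert abs(resid.sum()) < 1e-8

    def test_ssgblup_equals_blup_with_no_genotyped(self, small_population):
        pop = small_population
        vc = VarianceComponents(pop.sigma2_a, pop.sigma2_e)
        model = ModelSpec("trait", ("cg", "sex"))
        A_inv = build_A_inverse(pop.pedigree)
        empty = RelationshipMatrix(np.zeros((0, 0)), "H_correction", [])
        H = assemble_H_inverse(A_inv, empty)
        a = run_animal_model(model, pop.phenotypes, pop.pedigree, A_inv, vc, False)
        b = run_animal_model(model, pop.phenotypes, pop.pedigree, H, vc, False)
        assert np.abs(a.u_hat.to_numpy() - b.u_hat.to_numpy()).max() < 1e-10

    def test_single_level_factor_rejected(self):
        ped = founder_pedigree(4)
        data = dataset(ped.ids, [1.0, 2.0, 1.5, 0.5], cg=["c1"] * 4)
        with pytest.raises(ModelError, match="single level"):
            build_design(ModelSpec("trait", ("cg",)), data, ped)

    def test_empty_data_rejected(self):
        ped = founder_pedigree(2)
        data = TraitDataset(pd.DataFrame({"id": [], "trait": []}))
        with pytest.raises(ModelError, match="empty"):
            build_design(ModelSpec("trait", ()), data, ped)

    def test_duplicate_record_rejected(self):
        with pytest.raises(ModelError, match="more than one record"):
            TraitDataset(pd.DataFrame({"id": ["a", "a"], "trait": [1.0, 2.0]}))


class TestParentAverage:
    def test_trio_and_founders(self, trio):
        vc = VarianceComponents(0.5, 0.5)
        data = dataset(["S", "D"], [2.0, 1.0])
        res = run_pedigree_blup(NO_FIXED, data, trio, vc)
        pa = parent_average(res, trio)
        assert pa.loc["S"] == 0.0 and pa.loc["D"] == 0.0
        assert pa.loc["O"] == pytest.approx(
            (res.u_hat.loc["S"] + res.u_hat.loc["D"]) / 2.0)

    def test_hand_values(self, trio):
        res_u = pd.Series([2.0, 1.0, 0.0], index=trio.ids)
        fake = type("R", (), {"u_hat": res_u})()
        assert parent_average(fake, trio).loc["O"] == 1.5


class TestREML:
    def test_fixed_sigma2_a_matches_residual_moment_estimator(self):
        rng = np.random.default_rng(2)
        ped = make_random_pedigree(rng, 200)
        A = build_A(ped).dense()
        L = np.linalg.cholesky(A + 1e-10 * np.eye(ped.n))
        a = L @ rng.standard_normal(ped.n) * np.sqrt(0.4)
        y = 1.0 + a + rng.normal(0, np.sqrt(0.6), ped.n)
        data = dataset(ped.ids, y)
        model = ModelSpec("trait", factors=())
        K_inv = build_A_inverse(ped)
        vc = estimate_variance_components(model, data, ped, K_inv, fix_sigma2_a=0.4)
        assert vc.sigma2_a == 0.4

        # oracle: recompute the residual moment estimator from a fresh solve
        res = run_animal_model(model, data, ped, K_inv, vc, compute_pev=False)
        X, Z, yv, _ = build_design(model, data, ped)
        se = (yv @ yv - res.b_hat.to_numpy() @ (X.T @ yv)
              - res.u_hat.to_numpy() @ (Z.T @ yv)) / (len(yv) - 1)
        assert vc.sigma2_e == pytest.approx(se, abs=1e-3)

    def test_recovers_h2_on_model_generated_data(self):
        rng = np.random.default_rng(3)
        ests = []
        for rep in range(3):
            ped = make_random_pedigree(np.random.default_rng(10 + rep), 600)
            A = build_A(ped).dense()
            L = np.linalg.cholesky(A + 1e-10 * np.eye(ped.n))
            a = L @ rng.standard_normal(ped.n) * np.sqrt(0.5)
            y = a + rng.normal(0, np.sqrt(0.5), ped.n)
            vc = estimate_variance_components(
                ModelSpec("trait", ()), dataset(ped.ids, y), ped,
                build_A_inverse(ped))
            ests.append(vc.h2)
        assert abs(np.mean(ests) - 0.5) < 0.08
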