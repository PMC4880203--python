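"""REML likelihood correctness, optimizer behaviour and the eigen background."""

import numpy as np
import pytest

import epiqtl as eq
from epiqtl.varcomp import profiled_loglik_diagonal, reml_loglik
from oracles import eq4_style_loglik, ols_reml_loglik


def _sim(n, m, seed, **kw):
    cfg = eq.SimulationConfig(n=n, m=m, seed=seed, **kw)
    g = eq.simulate_genotypes(cfg)
    trait, _ = eq.simulate_phenotype(g, cfg)
    return g, trait, eq.compute_kinships(g)


class TestRemlLoglik:
    def test_lambda_zero_equals_closed_form_ols(self):
        _, trait, kin = _sim(40, 6, seed=21)
        ll, s2, _ = reml_loglik(np.zeros(6), trait, kin)
        ll_ref, s2_ref = ols_reml_loglik(trait.y, trait.X)
        assert ll == pytest.approx(ll_ref, abs=1e-8)
        assert s2 == pytest.approx(s2_ref, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_full_covariance_criterion(self, seed):
        # the profiled form equals the textbook criterion (all three terms
        # negative) evaluated at theta = lambda * sigma2_hat
        rng = np.random.default_rng(seed)
        _, trait, kin = _sim(30, 5, seed=100 + seed)
        lam = rng.uniform(0.0, 2.0, 6)
        ll, s2, _ = reml_loglik(lam, trait, kin)
        ll_ref = eq4_style_loglik(lam * s2, s2, trait.y, trait.X, kin.stacked())
        assert ll == pytest.approx(ll_ref, abs=1e-6)

    def test_translation_invariance_with_intercept(self):
        rng = np.random.default_rng(7)
        _, trait, kin = _sim(30, 5, seed=22)
        lam = rng.uniform(0, 1, 6)
        ll1, s1, _ = reml_loglik(lam, trait, kin)
        shifted = eq.TraitVector(trait.y + 17.3)
        ll2, s2, _ = reml_loglik(lam, shifted, kin)
        assert ll1 == pytest.approx(ll2, abs=1e-8)
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        g, trait, kin = _sim(25, 5, seed=23)
        lam = rng.uniform(0, 1, 6)
        perm = rng.permutation(25)
        gp = eq.CodedGenotypes(g.Z[perm], g.W[perm])
        kin_p = eq.compute_kinships(gp)
        trait_p = eq.TraitVector(trait.y[perm])
        ll1, _, _ = reml_loglik(lam, trait, kin)
        ll2, _, _ = reml_loglik(lam, trait_p, kin_p)
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_negative_lambda_rejected(self):
        _, trait, kin = _sim(20, 4, seed=24)
        with pytest.raises(ValueError, match="non-negative"):
            reml_loglik([-0.1, 0, 0, 0, 0, 0], trait, kin)


class TestEstimation:
    def test_estimates_respect_box_constraint(self):
        _, trait, kin = _sim(50, 8, seed=25)
        vc = eq.estimate_variance_components(trait, kin)
        assert np.all(vc.lam >= 0)
        assert vc.sigma2 > 0

    def test_component_variances_and_proportions(self):
        _, trait, kin = _sim(50, 8, seed=26)
        vc = eq.estimate_variance_components(trait, kin)
        assert np.array_equal(vc.component_variances, vc.lam * vc.sigma2)
        assert np.all(vc.proportions >= 0)
        assert vc.proportions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_phenotype_rejected(self):
        g, _, kin = _sim(20, 4, seed=27)
        flat = eq.TraitVector(np.full(20, 3.0))
        with pytest.raises(ValueError, match="zero variance"):
            eq.estimate_variance_components(flat, kin)

    def test_deterministic_given_inputs(self):
        _, trait, kin = _sim(40, 6, seed=28)
        vc1 = eq.estimate_variance_components(trait, kin)
        vc2 = eq.estimate_variance_components(trait, kin)
        assert np.array_equal(vc1.lam, vc2.lam)
        assert vc1.loglik == vc2.loglik

    def test_best_objective_monotone_over_trace(self):
        _, trait, kin = _sim(40, 6, seed=29)
        vc = eq.estimate_variance_components(trait, kin)
        best = np.minimum.accumulate(vc.trace)  # trace holds -loglik per eval
        assert np.all(np.diff(best) <= 0)

    def test_grid_search_oracle_single_kinship(self):
        # dense grid over the one free ratio; optimizer must land within one step
        g, _, kin = _sim(60, 30, seed=30)
        trait = eq.draw_polygenic_trait(
            kin, [2.0, 0, 0, 0, 0, 0], rng=np.random.default_rng(31)
        )
        grid = np.arange(0.0, 10.0001, 0.05)
        lls = [reml_loglik([l, 0, 0, 0, 0, 0], trait, kin)[0] for l in grid]
        lam_grid = grid[int(np.argmax(lls))]
        vc = eq.estimate_variance_components(trait, kin, components=("a",))
        assert abs(vc.lam[0] - lam_grid) <= 0.05 + 1e-9
        assert np.all(vc.lam[1:] == 0.0)

    def test_single_active_component_recovery(self):
        # true additive ratio 2: with only K_a free the estimate concentrates
        ests = []
        for rep in range(6):
            g, _, kin = _sim(120, 40, seed=400 + rep)
            trait = eq.draw_polygenic_trait(
                kin, [2.0, 0, 0, 0, 0, 0], rng=np.random.default_rng(500 + rep)
            )
            ests.append(eq.estimate_variance_components(trait, kin, components=("a",)).lam[0])
        assert 1.0 < np.mean(ests) < 3.5


class TestProportions:
    def test_pure_additive_ratio_one_gives_half(self, small_dataset):
        _, _, kin, _ = small_dataset
        vc = eq.VarianceComponents(
            lam=np.array([1.0, 0, 0, 0, 0, 0]), sigma2=2.0,
            component_variances=np.array([2.0, 0, 0, 0, 0, 0]),
            proportions=np.zeros(7), loglik=0.0, converged=True, n_iter=1,
        )
        shares = eq.variance_proportions(vc)
        assert shares[0] == pytest.approx(0.5)
        assert shares[6] == pytest.approx(0.5)
        assert np.all(shares[1:6] == 0)

    def test_null_model_all_residual(self):
        vc = eq.VarianceComponents(
            lam=np.zeros(6), sigma2=1.3,
            component_variances=np.zeros(6),
            proportions=np.zeros(7), loglik=0.0, converged=True, n_iter=1,
        )
        shares = eq.variance_proportions(vc)
        assert shares[6] == pytest.approx(1.0)


class TestBackgroundSpectrum:
    def test_rotation_orthonormal_and_reconstructs(self):
        rng = np.random.default_rng(9)
        _, trait, kin = _sim(50, 10, seed=32)
        lam = rng.uniform(0, 2, 6)
        bg = eq.weigh_and_eigendecompose(lam, kin, trait)
        U = bg.rotation
        assert np.max(np.abs(U.T @ U - np.eye(50))) < 1e-10
        G = np.tensordot(lam, kin.stacked(), axes=1)
        rec = U @ np.diag(bg.eigenvalues) @ U.T
        assert np.linalg.norm(rec - G) < 1e-8
        assert np.all(np.diff(bg.eigenvalues) <= 1e-12)  # non-increasing
        assert np.all(bg.eigenvalues >= 0)

    def test_null_background_at_lambda_zero(self):
        _, trait, kin = _sim(30, 6, seed=33)
        bg = eq.weigh_and_eigendecompose(np.zeros(6), kin, trait)
        assert np.all(bg.eigenvalues == 0)
        ll, _, _ = profiled_loglik_diagonal(
            bg.eigenvalues + 1.0, bg.y_star, bg.X_star
        )
        assert ll == pytest.approx(ols_reml_loglik(trait.y, trait.X)[0], abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_rotated_equals_direct_loglik(self, seed):
        rng = np.random.default_rng(seed)
        _, trait, kin = _sim(int(rng.integers(15, 40)), int(rng.integers(4, 9)),
                             seed=600 + seed)
        lam = rng.uniform(0, 2, 6)
        ll_direct, _, _ = reml_loglik(lam, trait, kin)
        bg = eq.weigh_and_eigendecompose(lam, kin, trait)
        ll_rot, _, _ = profiled_loglik_diagonal(
            bg.eigenvalues + 1.0, bg.y_star, bg.X_star
        )
        assert ll_rot == pytest.approx(ll_direct, abs=1e-6)
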