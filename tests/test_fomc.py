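"""First-order Monte Carlo REML: MC samples, BLUPs, and the f_r root."""

import numpy as np
import pytest

from slreml import (ParameterSpace, blup, dense_reml, draw_mc_phenotypes,
                    fit_fomc, fit_sldf, h2_to_tau, make_projector,
                    simulate_dataset, standardize_genotypes)
from slreml.fomc import _build_state, f_r
from slreml.genomatrix import StandardizedGenotypes
from slreml.lanczos import lanczos_seed
from slreml.genomatrix import ProjectedOperator, make_operator

SPACE = ParameterSpace()


@pytest.fixture(scope="module")
def instance():
    ds = simulate_dataset(150, 250, h2=0.5, c=3, seed=17)
    proj = make_projector(ds.X)
    return ds, proj


class TestMCSamples:
    def test_phenotypes_lie_in_projector_range(self, instance):
        ds, proj = instance
        s = draw_mc_phenotypes(ds.genotypes, proj, 6, seed=0)
        Y = s.phenotypes(1.7)
        assert np.max(np.abs(proj(Y) - Y)) <= 1e-12

    def test_trivial_projector_gives_plain_gaussian(self, rng):
        """With a covariate basis of zero practical extent the residual
        draws keep the identity covariance (degenerate configuration)."""
        Z = rng.standard_normal((500, 20))
        geno = StandardizedGenotypes(Z - Z.mean(0), np.arange(20), np.full(20, .3))
        X = np.zeros((500, 1))
        X[0, 0] = 1.0  # S = identity except coordinate 0
        proj = make_projector(X)
        s = draw_mc_phenotypes(geno, proj, 2000, seed=3)
        emp = s.residual @ s.residual.T / 2000
        Sd = proj.dense()
        assert np.max(np.abs(emp - Sd)) <= 3 * np.sqrt(2.0 / 2000) + 0.05

    def test_residual_covariance_matches_projector(self):
        n = 20
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((n, 10))
        geno = StandardizedGenotypes(Z - Z.mean(0), np.arange(10), np.full(10, .3))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        proj = make_projector(X)
        s = draw_mc_phenotypes(geno, proj, 5000, seed=8)
        emp = s.residual @ s.residual.T / 5000
        # entrywise MC SE for a projected Gaussian is ~ sqrt(2)/sqrt(reps)
        assert np.max(np.abs(emp - proj.dense())) <= 3 * np.sqrt(2.0 / 5000)

    def test_deterministic_given_seed(self, instance):
        ds, proj = instance
        a = draw_mc_phenotypes(ds.genotypes, proj, 4, seed=12)
        b = draw_mc_phenotypes(ds.genotypes, proj, 4, seed=12)
        np.testing.assert_array_equal(a.genetic, b.genetic)


@pytest.fixture(scope="module")
def blup_setup(instance):
    ds, proj = instance
    op = ProjectedOperator(make_operator(ds.genotypes, SPACE.tau0), proj)
    sy = proj(ds.y)
    fact = lanczos_seed(op, sy, tol=1e-9)
    return ds, proj, fact, sy


class TestBlup:

    @pytest.mark.parametrize("h2", [0.3, 0.6])
    def test_matches_dense_solves(self, blup_setup, h2):
        ds, proj, fact, sy = blup_setup
        tau = h2_to_tau(h2)
        n, m = ds.genotypes.n, ds.genotypes.m
        Sd = proj.dense()
        Hd = Sd @ ds.genotypes.grm() @ Sd + tau * np.eye(n)
        x = np.linalg.solve(Hd, sy)
        u_ref = ds.genotypes.Z.T @ (Sd @ x) / np.sqrt(m)
        e_ref = tau * x
        pair = blup(fact, SPACE.sigma(tau), tau, ds.genotypes)
        np.testing.assert_allclose(pair.u, u_ref, atol=1e-6 * np.linalg.norm(u_ref))
        np.testing.assert_allclose(pair.e, e_ref, atol=1e-6 * np.linalg.norm(e_ref))

    def test_ridge_shrinkage_limits(self, blup_setup):
        ds, proj, fact, sy = blup_setup
        tau_large = 1e6
        pair = blup(fact, SPACE.sigma(tau_large), tau_large, ds.genotypes)
        assert np.linalg.norm(pair.u) <= 1e-3
        np.testing.assert_allclose(pair.e, sy, atol=1e-3)

    def test_phenotype_in_covariate_space_gives_zero_blups(self, instance):
        ds, proj = instance
        op = ProjectedOperator(make_operator(ds.genotypes, SPACE.tau0), proj)
        sy = proj(ds.X @ np.ones(ds.X.shape[1]))
        assert np.linalg.norm(sy) <= 1e-10  # nothing left to predict from


@pytest.fixture(scope="module")
def root_state(instance):
    ds, _ = instance
    state, *_ = _build_state(ds.y, ds.X, ds.genotypes, SPACE, 40, 1e-7,
                             None, 23)
    return ds, state


class TestRootStatistic:
    def test_monotone_on_grid(self, root_state):
        """f_r is empirically monotone in tau on synthetic grids (an
        observation about these instances, not a theorem), so the bracketed
        root is unique."""
        _, state = root_state
        taus = [h2_to_tau(h) for h in (0.8, 0.6, 0.4, 0.2)]
        vals = [f_r(state, t) for t in taus]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_small_at_dense_oracle_optimum(self):
        """|f_r(tau_hat)| at the dense REML optimum is within 3 MC SE of 0
        across sample-set re-draws."""
        ds = simulate_dataset(400, 800, h2=0.5, c=3, seed=29)
        surf = dense_reml(ds.y, ds.X, ds.genotypes.grm())
        tau_hat = h2_to_tau(surf.h2_hat)
        vals = []
        for s in range(8):
            state, *_ = _build_state(ds.y, ds.X, ds.genotypes, SPACE, 50,
                                     5e-5, None, 700 + s)
            vals.append(f_r(state, tau_hat))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 3 * se


class TestFit:
    def test_requires_genotypes(self, instance):
        ds, _ = instance
        with pytest.raises(TypeError, match="genotype"):
            fit_fomc(ds.y, ds.X, ds.genotypes.grm())

    def test_agrees_with_dense_oracle(self, small_dataset):
        ds = small_dataset
        surf = dense_reml(ds.y, ds.X, ds.genotypes.grm())
        res = fit_fomc(ds.y, ds.X, ds.genotypes, n_rand=50, seed=3)
        assert res.h2 == pytest.approx(surf.h2_hat, abs=0.03)

    def test_agrees_with_sldf(self, small_dataset):
        """Both stochastic routes estimate the same quantity: their means
        over independent seeds agree within combined MC tolerances."""
        ds = small_dataset
        a = np.mean([fit_fomc(ds.y, ds.X, ds.genotypes, n_rand=50, seed=s).h2
                     for s in range(4, 8)])
        b = np.mean([fit_sldf(ds.y, ds.X, ds.genotypes, n_rand=50, seed=s).h2
                     for s in range(4, 8)])
        assert a == pytest.approx(b, abs=0.03)

    def test_root_converges_with_more_samples(self):
        """The f_r root approaches the dense optimum as n_rand grows."""
        ds = simulate_dataset(250, 500, h2=0.5, c=2, seed=37)
        surf = dense_reml(ds.y, ds.X, ds.genotypes.grm())
        errs = {nr: np.mean([abs(fit_fomc(ds.y, ds.X, ds.genotypes,
                                          n_rand=nr, seed=50 + s).h2
                                 - surf.h2_hat) for s in range(3)])
                for nr in (5, 100)}
        assert errs[100] < errs[5]

    def test_bitwise_reproducible(self, small_dataset):
        ds = small_dataset
        a = fit_fomc(ds.y, ds.X, ds.genotypes, n_rand=10, seed=88)
        b = fit_fomc(ds.y, ds.X, ds.genotypes, n_rand=10, seed=88)
        assert a.h2 == b.h2
        np.testing.assert_array_equal(a.blup_u, b.blup_u)

    def test_no_operator_applications_per_evaluation(self, small_dataset):
        ds = small_dataset
        from slreml.fomc import _build_state as build
        state, op, samples, iters, ok = build(ds.y, ds.X, ds.genotypes,
                                              SPACE, 10, 5e-5, None, 5)
        before_apply = op.n_apply
        before_zt = ds.genotypes.n_zt_products
        f_r(state, 1.3)
        assert op.n_apply == before_apply
        # exactly one Z^T product per BLUP of SNP effects: observed + n_rand
        assert ds.genotypes.n_zt_products - before_zt == 11

    def test_boundary_when_optimum_below_range(self):
        # seed chosen so the unconstrained optimum is negative; the root of
        # f_r then falls below h2_min and the fit lands on the lower bound
        ds = simulate_dataset(400, 800, h2=0.0, c=2, seed=12)
        res = fit_fomc(ds.y, ds.X, ds.genotypes, n_rand=15, seed=2)
        assert res.h2 <= 0.03
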