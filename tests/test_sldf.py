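"""Stochastic Lanczos derivative-free REML: criterion terms and the fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slreml import (ParameterSpace, dense_reml, exact_logdet,
                    exact_projected_quadform, fit_sldf, h2_to_tau,
                    profile_variance_components, quadratic_form,
                    reml_criterion, simulate_dataset, tau_to_h2)
from slreml.sldf import _build_state, covariate_logdet_term

SPACE = ParameterSpace()


class TestParameterMap:
    @pytest.mark.parametrize("h2,tau", [(0.5, 1.0), (0.25, 3.0), (0.8, 0.25)])
    def test_known_values(self, h2, tau):
        assert h2_to_tau(h2) == pytest.approx(tau)

    @given(st.floats(0.001, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, h2):
        assert tau_to_h2(h2_to_tau(h2)) == pytest.approx(h2, abs=1e-14)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            h2_to_tau(bad)

    def test_space_shift_nonnegative(self):
        sp = ParameterSpace(0.05, 0.9)
        for h2 in np.linspace(0.05, 0.9, 20):
            assert sp.sigma(h2_to_tau(h2)) >= 0.0


class TestProfileComponents:
    def test_formula(self):
        assert profile_variance_components(10.0, 1.0, 7, 2) == (2.0, 2.0)
        assert profile_variance_components(10.0, 3.0, 7, 2) == (2.0, 6.0)

    def test_h2_consistency(self):
        sg, se = profile_variance_components(5.0, 2.5, 100, 4)
        assert sg / (sg + se) == pytest.approx(tau_to_h2(2.5), abs=1e-14)

    def test_degenerate_phenotype(self):
        with pytest.raises(ValueError):
            profile_variance_components(0.0, 1.0, 10, 2)


@pytest.fixture(scope="module")
def state_and_data():
    ds = simulate_dataset(120, 240, h2=0.5, c=4, seed=21)
    state, op, iters, ok = _build_state(ds.y, ds.X, ds.genotypes, SPACE,
                                        n_rand=20, lanczos_tol=1e-7,
                                        max_iter=None, seed=4)
    return ds, state


class TestCriterionTerms:
    @pytest.mark.parametrize("h2", [0.3, 0.5, 0.7, 0.9])
    def test_quadratic_form_matches_explicit_k(self, state_and_data, h2):
        ds, state = state_and_data
        tau = h2_to_tau(h2)
        H = ds.genotypes.grm() + tau * np.eye(120)
        dense = exact_projected_quadform(ds.y, ds.X, H)
        assert quadratic_form(state, SPACE.sigma(tau)) == pytest.approx(
            dense, rel=1e-6)

    def test_quadratic_form_decreasing_in_shift(self, state_and_data):
        _, state = state_and_data
        vals = [quadratic_form(state, s) for s in (0.0, 0.5, 1.0, 3.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_phenotype_in_covariate_space_rejected(self, state_and_data):
        ds, _ = state_and_data
        y_bad = ds.X @ np.array([1.0, 0.5, -1.0, 2.0])
        with pytest.raises(ValueError, match="covariate column space"):
            _build_state(y_bad, ds.X, ds.genotypes, SPACE, 5, 5e-5, None, 0)

    @pytest.mark.parametrize("h2", [0.3, 0.6, 0.9])
    def test_covariate_logdet_matches_dense(self, state_and_data, h2):
        ds, state = state_and_data
        tau = h2_to_tau(h2)
        H = ds.genotypes.grm() + tau * np.eye(120)
        dense = exact_logdet(ds.X.T @ np.linalg.solve(H, ds.X))
        assert covariate_logdet_term(state, SPACE.sigma(tau)) == pytest.approx(
            dense, abs=1e-6)

    def test_scalar_covariate_logdet_closed_form(self):
        # H0 = 2I, X = e1: X^T H^{-1} X = 1/2
        n = 30
        y = np.arange(1.0, n + 1)
        X = np.zeros((n, 1))
        X[0, 0] = 1.0
        sp = ParameterSpace(0.5, 2.0 / 3.0)  # tau0 = 0.5
        state, *_ = _build_state(y, X, 1.5 * np.eye(n), sp, 3, 1e-9, None, 0)
        assert covariate_logdet_term(state, 0.0) == pytest.approx(
            np.log(0.5), abs=1e-8)

    def test_criterion_scale_invariance(self, state_and_data):
        """Rescaling y shifts the criterion by a constant; argmax unchanged."""
        ds, state = state_and_data
        state2, *_ = _build_state(3.0 * ds.y, ds.X, ds.genotypes, SPACE,
                                  n_rand=20, lanczos_tol=1e-7, max_iter=None,
                                  seed=4)
        h2s = np.array([0.2, 0.4, 0.6, 0.8])
        d = np.array([reml_criterion(state2, h) - reml_criterion(state, h)
                      for h in h2s])
        np.testing.assert_allclose(d, d[0], atol=1e-6)


class TestFit:
    def test_recovers_oracle_optimum(self, small_dataset):
        ds = small_dataset
        surf = dense_reml(ds.y, ds.X, ds.genotypes.grm())
        res = fit_sldf(ds.y, ds.X, ds.genotypes, n_rand=80, seed=2)
        assert res.h2 == pytest.approx(surf.h2_hat, abs=0.02)
        assert res.converged
        # result invariant: h2 reproduces the component ratio
        assert res.h2 == pytest.approx(
            res.sigma_g2 / (res.sigma_g2 + res.sigma_e2), abs=1e-10)

    def test_narrow_range_matches_wide_range(self, small_dataset):
        ds = small_dataset
        wide = fit_sldf(ds.y, ds.X, ds.genotypes, ParameterSpace(0.01, 0.99),
                        n_rand=30, seed=6)
        # anchor tau0 differs between the two spaces, so allow Lanczos-level
        # differences on top of the optimizer tolerance
        lo, hi = wide.h2 - 0.1, wide.h2 + 0.1
        narrow = fit_sldf(ds.y, ds.X, ds.genotypes, ParameterSpace(lo, hi),
                          n_rand=30, seed=6)
        assert narrow.h2 == pytest.approx(wide.h2, abs=5e-3)

    def test_grm_and_implicit_modes_identical(self):
        ds = simulate_dataset(200, 400, h2=0.5, c=3, seed=31)
        a = fit_sldf(ds.y, ds.X, ds.genotypes, n_rand=15, seed=9)
        b = fit_sldf(ds.y, ds.X, ds.genotypes.grm(), n_rand=15, seed=9)
        assert abs(a.h2 - b.h2) <= 1e-8

    def test_unidentifiable_grm_flagged(self, rng):
        y = rng.standard_normal(80)
        res = fit_sldf(y, np.ones((80, 1)), np.eye(80), n_rand=5, seed=0)
        assert "unidentifiable" in res.flags

    def test_zero_heritability_boundary_flagged(self):
        # seed chosen so the unconstrained optimum is negative (pure noise
        # can otherwise leave a small positive interior optimum)
        ds = simulate_dataset(400, 800, h2=0.0, c=2, seed=12)
        res = fit_sldf(ds.y, ds.X, ds.genotypes, n_rand=15, seed=1)
        assert "boundary" in res.flags
        assert res.h2 <= 0.03

    def test_zero_operator_applications_per_evaluation(self, small_dataset):
        ds = small_dataset
        from slreml.genomatrix import make_operator
        op = make_operator(ds.genotypes, SPACE.tau0)
        res = fit_sldf(ds.y, ds.X, op, SPACE, n_rand=10, seed=3)
        before = op.n_apply
        for h2 in (0.2, 0.45, 0.7):
            res.evaluate(h2)
        assert op.n_apply == before

    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset
        a = fit_sldf(ds.y, ds.X, ds.genotypes, n_rand=10, seed=77)
        b = fit_sldf(ds.y, ds.X, ds.genotypes, n_rand=10, seed=77)
        assert a.h2 == b.h2 and a.n_eval == b.n_eval


def test_criterion_difference_matches_dense_oracle():
    """l(0.3) - l(0.7) agrees with the exact profiled REML difference within
    3 SLQ standard errors over probe re-seeds."""
    ds = simulate_dataset(250, 500, h2=0.5, c=3, seed=8)
    surf = dense_reml(ds.y, ds.X, ds.genotypes.grm())
    exact_diff = surf.profile_loglik(0.3) - surf.profile_loglik(0.7)
    diffs = []
    for s in range(8):
        state, *_ = _build_state(ds.y, ds.X, ds.genotypes, SPACE, 60, 5e-5,
                                 None, 900 + s)
        diffs.append(reml_criterion(state, 0.3) - reml_criterion(state, 0.7))
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - exact_diff) <= 3 * se
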