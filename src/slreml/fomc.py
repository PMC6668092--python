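"""Lanczos first-order Monte Carlo REML.

The first-order (stationarity) conditions of the REML criterion equate the
squared norms of the BLUPs of the latent SNP effects and residuals,

    u~(tau) = m^{-1/2} Z^T S H'_tau^{-1} S y,   e~(tau) = tau H'_tau^{-1} S y,

with their model-implied conditional expectations, where
``H'_tau = (1/m) S Z Z^T S + tau I``.  The expectations are approximated by
Monte Carlo: latent draws ``u_k ~ N(0, I_m)`` and ``e_k ~ N(0, S)`` are
assembled into synthetic projected phenotypes

    y_k(tau) = m^{-1/2} S Z u_k + sqrt(tau) e_k,

whose covariance on range(S) is exactly H'_tau at unit genetic variance
(the overall scale cancels in the ratio statistic).  The root of

    f_r(tau) = ln[(u~'u~) / (e~'e~)] - ln[E_MC(u~'u~) / E_MC(e~'e~)]

is the REML estimate.  Each MC sample contributes its genetic and residual
parts as two separate Lanczos seed systems (2 n_rand + 1 systems in all),
so the tau-dependent reassembly above costs only two stored-basis solves
per sample; after the overhead round an f_r evaluation performs no operator
applications and exactly one Z^T product per BLUP of SNP effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .genomatrix import (ProjectedOperator, Projector, StandardizedGenotypes,
                         make_operator, make_projector)
from .lanczos import BlockFactorization, block_lanczos_seed, l_solve
from .results import REMLResults
from .sldf import ParameterSpace, h2_to_tau, profile_variance_components

logger = logging.getLogger(__name__)

__all__ = ["MCSampleSet", "BlupPair", "draw_mc_phenotypes", "blup", "f_r",
           "fit_fomc"]


@dataclass
class MCSampleSet:
    """Latent Monte Carlo draws and their projected phenotype parts.

    ``genetic`` holds the columns m^{-1/2} S Z u_k and ``residual`` the
    columns e_k = S g_k (g_k standard normal, so Cov(e_k) = S); the
    synthetic phenotype at variance ratio tau is
    genetic + sqrt(tau) * residual.  Both parts lie in range(S).
    """

    u_draws: np.ndarray    # (m, n_rand)
    genetic: np.ndarray    # (n, n_rand)
    residual: np.ndarray   # (n, n_rand)
    seed: object

    @property
    def n_rand(self) -> int:
        return self.genetic.shape[1]

    def phenotypes(self, tau: float = 1.0) -> np.ndarray:
        return self.genetic + np.sqrt(tau) * self.residual


@dataclass
class BlupPair:
    """Best linear unbiased predictions of SNP effects and residuals."""

    u: np.ndarray  # length m
    e: np.ndarray  # length n


def draw_mc_phenotypes(genotypes: StandardizedGenotypes, projector: Projector,
                       n_rand: int, seed) -> MCSampleSet:
    """Draw the latent Monte Carlo samples used by the root statistic."""
    if n_rand < 1:
        raise ValueError("n_rand must be at least 1")
    rng = np.random.default_rng(seed)
    n, m = genotypes.n, genotypes.m
    U = rng.standard_normal((m, n_rand))
    G = projector(genotypes.Z @ U) / np.sqrt(m)
    E = projector(rng.standard_normal((n, n_rand)))
    return MCSampleSet(u_draws=U, genetic=G, residual=E, seed=seed)


def blup(fact, sigma: float, tau: float, genotypes: StandardizedGenotypes) -> BlupPair:
    """BLUPs from a stored factorization of ``H'_{tau0} x = S y``.

    One shifted stored-basis solve plus a single Z^T product for the SNP
    effects; the residual BLUP is a scalar multiple of the solve.
    """
    x = l_solve(fact, sigma)  # lies in range(S), so Sx = x
    u = genotypes.zt_dot(x) / np.sqrt(genotypes.m)
    return BlupPair(u=u, e=tau * x)


@dataclass
class _RootState:
    """Stored factorizations and data for repeated f_r evaluation."""

    y_fact: object
    gen_facts: BlockFactorization
    res_facts: BlockFactorization
    genotypes: StandardizedGenotypes
    sy: np.ndarray
    space: ParameterSpace
    n: int
    c: int


def f_r(state: _RootState, tau: float) -> float:
    """Log-ratio root statistic; zero at REML stationary points."""
    if tau < state.space.tau0 - 1e-12:
        raise ValueError("tau below the anchor tau0")
    sigma = state.space.sigma(tau)
    m = state.genotypes.m
    x_y = l_solve(state.y_fact, sigma)
    # H'^{-1} y_k(tau) = solve(genetic_k) + sqrt(tau) solve(residual_k)
    Xmc = np.stack(
        [l_solve(g, sigma) + np.sqrt(tau) * l_solve(r, sigma)
         for g, r in zip(state.gen_facts, state.res_facts)], axis=1)
    # one Z^T product per BLUP of SNP effects (observed + n_rand MC columns)
    U_all = state.genotypes.zt_dot(np.column_stack([x_y, Xmc])) / np.sqrt(m)
    uu = float(U_all[:, 0] @ U_all[:, 0])
    ee = tau ** 2 * float(x_y @ x_y)
    e_uu = float(np.mean(np.sum(U_all[:, 1:] ** 2, axis=0)))
    e_ee = tau ** 2 * float(np.mean(np.sum(Xmc ** 2, axis=0)))
    if min(uu, ee, e_uu, e_ee) <= 0.0:
        raise ValueError("degenerate quadratic term in f_r")
    return float(np.log(uu / ee) - np.log(e_uu / e_ee))


def _build_state(y, X, genotypes, space, n_rand, lanczos_tol, max_iter, seed):
    if not isinstance(genotypes, StandardizedGenotypes):
        raise TypeError("first-order Monte Carlo REML requires the genotype "
                        "matrix; a precomputed GRM is not sufficient")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, c = X.shape
    projector = make_projector(X)
    sy = projector(y)
    if np.linalg.norm(sy) <= 1e-12 * max(np.linalg.norm(y), 1.0):
        raise ValueError("phenotype lies in the covariate column space")
    mc_seed, = np.random.SeedSequence(seed).spawn(1)
    samples = draw_mc_phenotypes(genotypes, projector, n_rand, mc_seed)
    op = ProjectedOperator(make_operator(genotypes, space.tau0), projector)
    # overhead round: 2 n_rand + 1 seed systems over H'_{tau0}
    seeds = np.column_stack([sy, samples.genetic, samples.residual])
    facts = block_lanczos_seed(op, seeds, tol=lanczos_tol, max_iter=max_iter)
    y_fact = facts[0]
    gen_facts = BlockFactorization(facts.factorizations[1:1 + n_rand])
    res_facts = BlockFactorization(facts.factorizations[1 + n_rand:])
    state = _RootState(y_fact=y_fact, gen_facts=gen_facts, res_facts=res_facts,
                       genotypes=genotypes, sy=sy, space=space, n=n, c=c)
    iters = {
        "phenotype": [y_fact.n_iter],
        "mc_genetic": [f.n_iter for f in gen_facts],
        "mc_residual": [f.n_iter for f in res_facts],
    }
    return state, op, samples, iters, facts.converged


def fit_fomc(y, X, genotypes: StandardizedGenotypes,
             space: ParameterSpace | None = None, n_rand: int = 15,
             lanczos_tol: float = 5e-5, opt_tol: float = 1e-5,
             max_iter: int | None = None, seed=0,
             return_blups: bool = True) -> REMLResults:
    """Fit the two-component model by Lanczos first-order Monte Carlo REML.

    Root-finds f_r over the heritability scale with Brent's bracketed
    method to absolute tolerance ``opt_tol``.  If f_r does not change sign
    over the bracket the fit returns the better endpoint flagged
    ``"no_root_in_range"`` and ``"boundary"``.
    """
    space = space or ParameterSpace()
    state, op, samples, iters, lanczos_ok = _build_state(
        y, X, genotypes, space, n_rand, lanczos_tol, max_iter, seed)
    flags = [] if lanczos_ok else ["lanczos_not_converged"]

    n_eval = 0

    def g(h2: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return f_r(state, h2_to_tau(h2))

    f_lo, f_hi = g(space.h2_min), g(space.h2_max)
    converged = lanczos_ok
    if f_lo == 0.0:
        h2_hat = space.h2_min
    elif f_hi == 0.0:
        h2_hat = space.h2_max
    elif np.sign(f_lo) == np.sign(f_hi):
        flags += ["no_root_in_range", "boundary"]
        h2_hat = space.h2_min if abs(f_lo) < abs(f_hi) else space.h2_max
        converged = False
        logger.warning("f_r has no sign change on [%g, %g]; returning "
                       "boundary value", space.h2_min, space.h2_max)
    else:
        h2_hat = float(brentq(g, space.h2_min, space.h2_max, xtol=opt_tol))
    tau_hat = h2_to_tau(h2_hat)
    sigma_hat = space.sigma(tau_hat)
    ypy = float(state.sy @ l_solve(state.y_fact, sigma_hat))
    sigma_g2, sigma_e2 = profile_variance_components(ypy, tau_hat, state.n, state.c)
    blups = blup(state.y_fact, sigma_hat, tau_hat, genotypes) if return_blups else None
    return REMLResults(
        method="fomc", h2=h2_hat, sigma_g2=sigma_g2, sigma_e2=sigma_e2,
        loglik=None, n_eval=n_eval, lanczos_iters=iters,
        n=state.n, c=state.c, m=genotypes.m, n_rand=n_rand, seed=seed,
        h2_bounds=(space.h2_min, space.h2_max), converged=converged,
        flags=flags,
        blup_u=None if blups is None else blups.u,
        blup_e=None if blups is None else blups.e,
        _evaluator=lambda h2: f_r(state, h2_to_tau(h2)))
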