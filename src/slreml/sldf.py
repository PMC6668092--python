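"""Stochastic Lanczos derivative-free REML.

One round of (block) Lanczos work at the anchor variance ratio
``tau_0 = (1 - h2_max) / h2_max`` produces

* a factorization of the projected phenotype system ``(S H_0 S) x = S y``
  (the quadratic-form term),
* factorizations of the c covariate systems ``H_0 x = x_j`` (the
  ``ln det(X^T H_tau^{-1} X)`` correction term), and
* quadrature rules from Rademacher probes over ``H_0`` (the SLQ estimate of
  ``ln det(H_tau)``).

Because every parameter value ``tau`` in the search range maps to a
*nonnegative* shift ``sigma = tau - tau_0``, the profiled REML criterion

    l(h2) = -(n - c) ln(y^T P_tau y) - [ln det(H_tau) + ln det(X^T H_tau^{-1} X)]

can thereafter be evaluated with vector operations alone, and is maximized
over h2 by Brent's method.  The constant ``ln det(X^T X)`` is omitted
throughout (it does not depend on tau).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .genomatrix import (GenomicOperator, ProjectedOperator, make_operator,
                         make_projector)
from .lanczos import BlockFactorization, LanczosFactorization, block_lanczos_seed, l_solve
from .results import REMLResults
from .slq import QuadratureRule, draw_probes

logger = logging.getLogger(__name__)

__all__ = ["ParameterSpace", "CriterionState", "h2_to_tau", "tau_to_h2",
           "quadratic_form", "covariate_logdet_term",
           "profile_variance_components", "reml_criterion", "fit_sldf"]

#: heritability distance from a bound below which an optimum is flagged
BOUNDARY_FACTOR = 10.0
#: criterion spread below which the likelihood is declared flat
FLAT_TOL = 1e-6


def h2_to_tau(h2: float) -> float:
    """Variance ratio tau = sigma_e^2 / sigma_g^2 = (1 - h2) / h2."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie strictly inside (0, 1)")
    return (1.0 - h2) / h2


def tau_to_h2(tau: float) -> float:
    """Inverse map h2 = 1 / (1 + tau)."""
    if tau < 0.0:
        raise ValueError("tau must be nonnegative")
    return 1.0 / (1.0 + tau)


@dataclass(frozen=True)
class ParameterSpace:
    """Heritability search range and its shifted-family parametrization.

    Anchoring the base operator at ``h2_max`` makes every evaluated shift
    nonnegative and every H_tau in the range at least as well conditioned
    as H_0.
    """

    h2_min: float = 0.01
    h2_max: float = 0.99

    def __post_init__(self):
        if not 0.0 < self.h2_min < self.h2_max < 1.0:
            raise ValueError("need 0 < h2_min < h2_max < 1")

    @property
    def tau0(self) -> float:
        return h2_to_tau(self.h2_max)

    def sigma(self, tau: float) -> float:
        s = tau - self.tau0
        if s < -1e-12:
            raise ValueError(f"tau={tau} falls below the anchor tau0={self.tau0}")
        return max(s, 0.0)


@dataclass
class CriterionState:
    """Everything the criterion needs after the one-time Lanczos round."""

    y_fact: LanczosFactorization     # seed Sy over the projected operator
    cov_facts: BlockFactorization    # seeds = columns of X over H_0
    quad_rule: QuadratureRule        # probes over H_0
    sy: np.ndarray
    X: np.ndarray
    space: ParameterSpace
    n: int
    c: int


def quadratic_form(state: CriterionState, sigma: float) -> float:
    """y^T P_tau y via the projected seed system (Lemma-1 route):
    (Sy)^T (S H_0 S + sigma I)^{-1} (Sy), vector work only."""
    x = l_solve(state.y_fact, sigma)
    return float(state.sy @ x)


def covariate_logdet_term(state: CriterionState, sigma: float) -> float:
    """ln det(X^T H_tau^{-1} X) from the c stored covariate factorizations."""
    W = np.stack([l_solve(f, sigma) for f in state.cov_facts], axis=1)
    M = state.X.T @ W
    M = (M + M.T) / 2.0
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X^T H^{-1} X is not positive definite; covariate Lanczos solves "
            "have not converged") from exc
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def profile_variance_components(ypy: float, tau: float, n: int, c: int) -> tuple[float, float]:
    """Profiled variance components implied by the REML stationarity
    conditions: sigma_g^2 = y^T P_tau y / (n - c), sigma_e^2 = tau sigma_g^2."""
    if ypy <= 0.0:
        raise ValueError("quadratic form is nonpositive; degenerate phenotype")
    if n <= c:
        raise ValueError("need n > c")
    sigma_g2 = ypy / (n - c)
    return sigma_g2, tau * sigma_g2


def reml_criterion(state: CriterionState, h2: float) -> float:
    """Profiled REML log-likelihood at h2, up to an additive constant."""
    tau = h2_to_tau(h2)
    sigma = state.space.sigma(tau)
    ypy = quadratic_form(state, sigma)
    if ypy <= 0.0:
        raise ValueError("quadratic form is nonpositive; degenerate phenotype")
    logdet = state.quad_rule.logdet(sigma) + covariate_logdet_term(state, sigma)
    return -(state.n - state.c) * np.log(ypy) - logdet


def _build_state(y, X, source, space, n_rand, lanczos_tol, max_iter, seed):
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, c = X.shape
    op = source if isinstance(source, GenomicOperator) else make_operator(source, space.tau0)
    if abs(op.tau0 - space.tau0) > 1e-12:
        raise ValueError("operator base shift does not match the parameter space")
    projector = make_projector(X)
    sy = projector(y)
    if np.linalg.norm(sy) <= 1e-12 * max(np.linalg.norm(y), 1.0):
        raise ValueError("phenotype lies in the covariate column space")
    probe_seed, = np.random.SeedSequence(seed).spawn(1)
    probes = draw_probes(n, n_rand, probe_seed)
    # one overhead round: probes and covariates over H_0, phenotype over S H_0 S
    base_facts = block_lanczos_seed(op, np.column_stack([probes.vectors, X]),
                                    tol=lanczos_tol, max_iter=max_iter)
    probe_facts = BlockFactorization(base_facts.factorizations[:n_rand])
    cov_facts = BlockFactorization(base_facts.factorizations[n_rand:])
    proj_op = ProjectedOperator(op, projector)
    y_fact = block_lanczos_seed(proj_op, sy[:, None], tol=lanczos_tol,
                                max_iter=max_iter)[0]
    rule = QuadratureRule.from_factorizations(probe_facts, n)
    state = CriterionState(y_fact=y_fact, cov_facts=cov_facts, quad_rule=rule,
                           sy=sy, X=X, space=space, n=n, c=c)
    iters = {
        "probes": [f.n_iter for f in probe_facts],
        "covariates": [f.n_iter for f in cov_facts],
        "phenotype": [y_fact.n_iter],
    }
    converged = base_facts.converged and y_fact.converged
    return state, op, iters, converged


def fit_sldf(y, X, source, space: ParameterSpace | None = None,
             n_rand: int = 15, lanczos_tol: float = 5e-5,
             opt_tol: float = 1e-5, max_iter: int | None = None,
             seed=0) -> REMLResults:
    """Fit the two-component model by stochastic Lanczos derivative-free REML.

    ``source`` may be a StandardizedGenotypes (implicit mode), a dense GRM
    matrix (explicit mode), or a prebuilt GenomicOperator anchored at the
    space's tau0.  After the overhead Lanczos round, each criterion
    evaluation costs O(n c k) vector operations and zero applications of the
    genomic operator.
    """
    space = space or ParameterSpace()
    state, op, iters, lanczos_ok = _build_state(
        y, X, source, space, n_rand, lanczos_tol, max_iter, seed)
    flags = [] if lanczos_ok else ["lanczos_not_converged"]

    n_eval = 0

    def objective(h2: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return -reml_criterion(state, h2)

    # cheap flatness scan: an unidentifiable instance (GRM proportional to I)
    # has an exactly constant criterion
    scan = np.linspace(space.h2_min, space.h2_max, 5)
    scan_vals = np.array([-objective(h) for h in scan])
    if scan_vals.max() - scan_vals.min() < FLAT_TOL:
        flags.append("unidentifiable")
        logger.warning("REML criterion is flat over the search range; "
                       "heritability is not identified")

    res = minimize_scalar(objective, bounds=(space.h2_min, space.h2_max),
                          method="bounded",
                          options={"xatol": opt_tol, "maxiter": 100})
    h2_hat = float(res.x)
    if min(h2_hat - space.h2_min, space.h2_max - h2_hat) <= BOUNDARY_FACTOR * opt_tol:
        flags.append("boundary")
    tau_hat = h2_to_tau(h2_hat)
    ypy = quadratic_form(state, space.sigma(tau_hat))
    sigma_g2, sigma_e2 = profile_variance_components(ypy, tau_hat, state.n, state.c)
    m = op.genotypes.m if op.mode == "implicit_genotype" else None
    return REMLResults(
        method="sldf", h2=h2_hat, sigma_g2=sigma_g2, sigma_e2=sigma_e2,
        loglik=float(-res.fun), n_eval=n_eval, lanczos_iters=iters,
        n=state.n, c=state.c, m=m, n_rand=n_rand, seed=seed,
        h2_bounds=(space.h2_min, space.h2_max),
        converged=bool(res.success) and lanczos_ok, flags=flags,
        _evaluator=lambda h2: reml_criterion(state, h2))
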