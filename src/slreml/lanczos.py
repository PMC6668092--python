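"""Seed and block Lanczos factorizations with O(n) shifted solves.

The Lanczos process applied to the seed system ``A x = b`` yields an
orthonormal Krylov basis ``U`` and a symmetric tridiagonal Jacobi matrix
``T`` with ``A U = U T`` (up to the trailing residual term).  Because Krylov
subspaces are shift invariant, the same factorization solves every member of
the shifted family ``(A + sigma I) x = b`` for ``sigma >= 0`` using nothing
but small tridiagonal solves and one basis combination — no further operator
applications.  This is the single structural fact both REML algorithms in
this package are built on.

Bases are stored with full reorthogonalization: they are needed anyway for
the shifted solves, and the Gaussian-quadrature weights extracted from ``T``
degrade badly without it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded

logger = logging.getLogger(__name__)

__all__ = [
    "LanczosFactorization",
    "BlockFactorization",
    "lanczos_seed",
    "block_lanczos_seed",
    "l_solve",
    "shifted_residual_norm",
]

#: relative off-diagonal threshold below which the Krylov subspace is
#: declared invariant ("happy breakdown")
BREAKDOWN_RTOL = 1e-13


@dataclass
class LanczosFactorization:
    """Stored Lanczos factorization of one seed system ``A x = b``."""

    basis: np.ndarray            # (n, k) orthonormal columns
    alpha: np.ndarray            # (k,) diagonal of T
    beta: np.ndarray             # (k-1,) off-diagonal of T
    seed_norm: float
    residual_history: np.ndarray  # CG residual 2-norm after each step
    converged: bool
    breakdown: bool = False

    @property
    def n_iter(self) -> int:
        return self.alpha.shape[0]

    @property
    def delta(self) -> float:
        """Last diagonal Jacobi element, the shift-contraction coefficient."""
        return float(self.alpha[-1])

    def jacobi(self) -> np.ndarray:
        """Dense Jacobi matrix T (diagnostics only; k is small)."""
        k = self.n_iter
        T = np.diag(self.alpha)
        if k > 1:
            T[np.arange(k - 1), np.arange(1, k)] = self.beta
            T[np.arange(1, k), np.arange(k - 1)] = self.beta
        return T


@dataclass
class BlockFactorization:
    """Per-column Lanczos factorizations sharing one operator."""

    factorizations: list
    converged: bool = field(init=False)

    def __post_init__(self):
        self.converged = all(f.converged for f in self.factorizations)

    def __getitem__(self, j: int) -> LanczosFactorization:
        return self.factorizations[j]

    def __len__(self) -> int:
        return len(self.factorizations)

    def __iter__(self):
        return iter(self.factorizations)


def _tridiag_solve_e1(alpha: np.ndarray, beta: np.ndarray, sigma: float = 0.0) -> np.ndarray:
    """Solve (T + sigma I) t = e1 for symmetric positive definite tridiagonal T."""
    k = alpha.shape[0]
    if k == 1:
        d = alpha[0] + sigma
        if d <= 0:
            raise np.linalg.LinAlgError(
                f"shifted Jacobi matrix is not positive definite (sigma={sigma})")
        return np.array([1.0 / d])
    ab = np.zeros((2, k))
    ab[0, 1:] = beta
    ab[1, :] = alpha + sigma
    e1 = np.zeros(k)
    e1[0] = 1.0
    try:
        return solveh_banded(ab, e1)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"shifted Jacobi matrix is numerically singular (sigma={sigma})") from exc


class _SeedState:
    """Mutable per-seed state for the (block) Lanczos iteration."""

    __slots__ = ("u_prev", "u_cur", "alphas", "betas", "seed_norm",
                 "residuals", "basis", "active", "converged", "breakdown")

    def __init__(self, b: np.ndarray):
        self.seed_norm = float(np.linalg.norm(b))
        if self.seed_norm == 0.0:
            raise ValueError("Lanczos seed vector is zero")
        self.u_cur = b / self.seed_norm
        self.u_prev = None
        self.alphas: list[float] = []
        self.betas: list[float] = []
        self.residuals: list[float] = []
        self.basis: list[np.ndarray] = [self.u_cur]
        self.active = True
        self.converged = False
        self.breakdown = False

    def step(self, w: np.ndarray, tol: float) -> None:
        """Advance one Lanczos step given w = A @ u_cur."""
        alpha = float(self.u_cur @ w)
        w = w - alpha * self.u_cur
        if self.u_prev is not None:
            w = w - self.betas[-1] * self.u_prev
        # full reorthogonalization, two classical Gram-Schmidt passes
        B = np.stack(self.basis, axis=1)
        w = w - B @ (B.T @ w)
        w = w - B @ (B.T @ w)
        beta = float(np.linalg.norm(w))
        self.alphas.append(alpha)
        k = len(self.alphas)
        t = _tridiag_solve_e1(np.asarray(self.alphas), np.asarray(self.betas))
        res = self.seed_norm * beta * abs(t[-1])
        self.residuals.append(res)
        if res < tol:
            self.converged = True
            self.active = False
            return
        if beta <= BREAKDOWN_RTOL * self.seed_norm:
            # invariant subspace captured: the solve is (numerically) exact
            self.converged = True
            self.breakdown = True
            self.active = False
            return
        self.betas.append(beta)
        self.u_prev = self.u_cur
        self.u_cur = w / beta
        self.basis.append(self.u_cur)

    def finish(self, max_iter: int) -> LanczosFactorization:
        if self.active:  # ran out of iterations
            self.active = False
            # drop the trailing basis vector that has no alpha yet
            if len(self.basis) == len(self.alphas) + 1:
                self.basis.pop()
                self.betas.pop()
            logger.warning("Lanczos did not converge in %d steps "
                           "(final residual %.3e)", max_iter, self.residuals[-1])
        basis = np.stack(self.basis, axis=1)
        return LanczosFactorization(
            basis=basis,
            alpha=np.asarray(self.alphas),
            beta=np.asarray(self.betas[: len(self.alphas) - 1]),
            seed_norm=self.seed_norm,
            residual_history=np.asarray(self.residuals),
            converged=self.converged,
            breakdown=self.breakdown,
        )


def lanczos_seed(A, b: np.ndarray, tol: float = 5e-5,
                 max_iter: int | None = None) -> LanczosFactorization:
    """Run the Lanczos process on the seed system ``A x = b``.

    Iterates until the conjugate-gradient residual 2-norm of ``A x = b``
    drops below ``tol`` (absolute) or ``max_iter`` is reached; in the latter
    case the factorization is returned flagged, not raised.
    """
    b = np.asarray(b, dtype=float)
    n = b.shape[0]
    if max_iter is None:
        max_iter = min(n, 1000)
    state = _SeedState(b)
    for _ in range(max_iter):
        if not state.active:
            break
        state.step(A.matvec(state.u_cur), tol)
    return state.finish(max_iter)


def block_lanczos_seed(A, B: np.ndarray, tol: float = 5e-5,
                       max_iter: int | None = None) -> BlockFactorization:
    """Lanczos factorizations for every column of ``B``, stepped jointly.

    Mathematically identical to running :func:`lanczos_seed` per column; the
    operator is applied to all still-active columns at once (one BLAS-3
    product per step), and convergence is declared when the largest
    per-column residual drops below ``tol``.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if B.ndim != 2:
        raise ValueError("B must be a 2-d array of right-hand sides")
    n, p = B.shape
    if max_iter is None:
        max_iter = min(n, 1000)
    states = []
    for j in range(p):
        if np.linalg.norm(B[:, j]) == 0.0:
            raise ValueError(f"right-hand-side column {j} is zero")
        states.append(_SeedState(B[:, j]))
    for _ in range(max_iter):
        active = [s for s in states if s.active]
        if not active:
            break
        W = A.matmat(np.stack([s.u_cur for s in active], axis=1))
        for jj, s in enumerate(active):
            s.step(W[:, jj], tol)
    return BlockFactorization([s.finish(max_iter) for s in states])


def l_solve(fact: LanczosFactorization, sigma: float) -> np.ndarray:
    """CG approximate solution of ``(A + sigma I) x = b`` from the stored
    factorization of the seed system — O(n k) vector work, zero operator
    applications.

    At ``sigma = 0`` this is exactly the seed CG iterate.
    """
    if sigma < 0:
        raise ValueError("negative shifts are outside the shifted family")
    t = _tridiag_solve_e1(fact.alpha, fact.beta, sigma)
    return fact.seed_norm * (fact.basis @ t)


def shifted_residual_norm(fact: LanczosFactorization, sigma: float) -> float:
    """Predicted residual norm of the shifted solve,
    ``delta / (delta + sigma)`` times the seed residual norm.

    Exact at ``sigma = 0``; for ``sigma > 0`` a cheap convergence predictor
    that never exceeds the seed residual norm.
    """
    if fact.residual_history.size == 0:
        raise ValueError("empty factorization")
    if sigma < 0:
        raise ValueError("negative shifts are outside the shifted family")
    delta = fact.delta
    return float(fact.residual_history[-1] * delta / (delta + sigma))
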