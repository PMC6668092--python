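"""Stochastic Lanczos quadrature for the shifted log-determinant family.

``ln det(H_0 + sigma I)`` is the trace of the matrix logarithm, estimated by
a Hutchinson-type average of Gaussian quadratures: for each normalized
Rademacher probe the Lanczos Jacobi matrix supplies nodes (its eigenvalues)
and weights (squared first eigenvector components) approximating the
Riemann-Stieltjes integral of ln against the probe's spectral measure.
A shift translates the nodes, so the whole shifted family is covered by one
set of factorizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh_tridiagonal

from .lanczos import BlockFactorization, LanczosFactorization

__all__ = ["ProbeSet", "QuadratureRule", "draw_probes", "jacobi_quadrature", "slq_logdet"]


@dataclass
class ProbeSet:
    """Normalized Rademacher probe vectors, entries +-1/sqrt(n)."""

    vectors: np.ndarray  # (n, n_rand)
    seed: object

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_rand(self) -> int:
        return self.vectors.shape[1]


def draw_probes(n: int, n_rand: int, seed) -> ProbeSet:
    """Draw ``n_rand`` i.i.d. normalized Rademacher probes of length ``n``."""
    if n_rand < 1:
        raise ValueError("n_rand must be at least 1")
    rng = np.random.default_rng(seed)
    V = (2.0 * rng.integers(0, 2, size=(n, n_rand)) - 1.0) / np.sqrt(n)
    return ProbeSet(V, seed)


def jacobi_quadrature(fact: LanczosFactorization) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian quadrature nodes and weights from one Jacobi matrix.

    Nodes are the eigenvalues of the tridiagonal T; weight l is the squared
    first component of eigenvector l, so the weights sum to one.
    """
    if fact.n_iter < 1:
        raise ValueError("factorization has no steps")
    nodes, vecs = eigh_tridiagonal(fact.alpha, fact.beta)
    weights = vecs[0, :] ** 2
    return nodes, weights


class QuadratureRule:
    """Shift-updatable quadrature for ``ln det(H_0 + sigma I)``.

    Holds one (nodes, weights) pair per probe; evaluating at a shift is pure
    vector arithmetic.
    """

    def __init__(self, nodes: list[np.ndarray], weights: list[np.ndarray], n: int):
        self.nodes = [np.asarray(t, dtype=float) for t in nodes]
        self.weights = [np.asarray(w, dtype=float) for w in weights]
        self.n = int(n)
        self.n_rand = len(self.nodes)

    @classmethod
    def from_factorizations(cls, facts, n: int) -> "QuadratureRule":
        if isinstance(facts, BlockFactorization):
            facts = list(facts)
        pairs = [jacobi_quadrature(f) for f in facts]
        return cls([p[0] for p in pairs], [p[1] for p in pairs], n)

    def logdet(self, sigma: float) -> float:
        """(n / n_rand) * sum_k sum_l w_{k,l} ln(theta_{k,l} + sigma)."""
        total = 0.0
        for theta, w in zip(self.nodes, self.weights):
            shifted = theta + sigma
            if np.any(shifted <= 0.0):
                raise ValueError(
                    f"operator is not positive definite at shift {sigma}")
            total += float(w @ np.log(shifted))
        return self.n / self.n_rand * total


def slq_logdet(rule: QuadratureRule, sigma: float) -> float:
    """Stochastic Lanczos quadrature estimate of ``ln det(H_0 + sigma I)``."""
    return rule.logdet(sigma)
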