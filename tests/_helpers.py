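"""Shared test utilities."""

import numpy as np


class DenseOperator:
    """Minimal operator wrapper over a dense symmetric matrix, with the same
    application-counting interface as the genomic operators."""

    def __init__(self, A):
        self.A = np.asarray(A, dtype=float)
        self.n = self.A.shape[0]
        self.n_apply = 0

    def matvec(self, v):
        v = np.asarray(v)
        self.n_apply += 1 if v.ndim == 1 else v.shape[1]
        return self.A @ v

    matmat = matvec


def random_spd(n, rng, cond=50.0):
    """Random SPD matrix with spectrum in [1/cond, 1] * scale."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    lam = np.linspace(1.0 / cond, 1.0, n)
    return (Q * lam) @ Q.T
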