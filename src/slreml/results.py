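"""Result container shared by all REML fitting routes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["REMLResults"]


@dataclass
class REMLResults:
    """Estimates and diagnostics from one REML fit.

    ``loglik`` is the profiled log-likelihood up to an additive constant
    (None for the first-order route, which never evaluates it).
    ``lanczos_iters`` maps seed-group names to per-seed iteration counts.
    """

    method: str
    h2: float
    sigma_g2: float
    sigma_e2: float
    loglik: float | None
    n_eval: int
    lanczos_iters: dict
    n: int
    c: int
    m: int | None
    n_rand: int | None
    seed: object
    h2_bounds: tuple
    converged: bool
    flags: list = field(default_factory=list)
    blup_u: np.ndarray | None = None
    blup_e: np.ndarray | None = None
    _evaluator: object = field(default=None, repr=False)

    @property
    def tau(self) -> float:
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf

    def evaluate(self, h2: float) -> float:
        """Re-evaluate the fitted objective (criterion or root statistic) at
        another heritability — vector work only, no operator applications."""
        if self._evaluator is None:
            raise ValueError("no evaluator attached to this result")
        return self._evaluator(h2)

    def summary(self) -> str:
        total_iters = sum(int(np.sum(v)) for v in self.lanczos_iters.values())
        lines = [
            "REML variance component estimates",
            "=" * 46,
            f"method:            {self.method}",
            f"samples (n):       {self.n}",
            f"covariates (c):    {self.c}",
            f"markers (m):       {self.m if self.m is not None else 'n/a (GRM input)'}",
            "-" * 46,
            f"h2                 {self.h2:.6f}",
            f"sigma_g2           {self.sigma_g2:.6f}",
            f"sigma_e2           {self.sigma_e2:.6f}",
            f"tau (=se2/sg2)     {self.tau:.6f}",
            f"loglik (+const)    "
            f"{'n/a' if self.loglik is None else format(self.loglik, '.4f')}",
            "-" * 46,
            f"objective evals:   {self.n_eval}",
            f"lanczos iters:     {total_iters} total over "
            f"{sum(len(np.atleast_1d(v)) for v in self.lanczos_iters.values())} seeds",
            f"n_rand:            {self.n_rand}",
            f"h2 bounds:         [{self.h2_bounds[0]}, {self.h2_bounds[1]}]",
            f"converged:         {self.converged}",
            f"flags:             {', '.join(self.flags) if self.flags else 'none'}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "h2": self.h2,
            "sigma_g2": self.sigma_g2,
            "sigma_e2": self.sigma_e2,
            "logL_const": self.loglik,
            "n_eval": self.n_eval,
            "lanczos_iters": {k: np.asarray(v).tolist()
                              for k, v in self.lanczos_iters.items()},
            "warnings": list(self.flags),
        }
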