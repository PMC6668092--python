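"""Model/results front end for genomic variance-component REML.

``HeritabilityModel`` bundles a phenotype, covariates, and genomic data
(genotypes or a precomputed GRM); ``fit`` dispatches to the stochastic
Lanczos derivative-free route, the first-order Monte Carlo route, or the
dense deterministic reference, all of which return :class:`REMLResults`.
"""

from __future__ import annotations

import numpy as np

from . import io as _io
from .fomc import fit_fomc
from .genomatrix import (RawGenotypes, StandardizedGenotypes,
                         standardize_genotypes)
from .oracle import dense_reml
from .results import REMLResults
from .sldf import ParameterSpace, fit_sldf, h2_to_tau

__all__ = ["HeritabilityModel"]


class HeritabilityModel:
    """Two-variance-component genomic linear mixed model,

        y = X beta + (1/sqrt(m)) Z u + e,
        u ~ N(0, sigma_g^2 I_m),  e ~ N(0, sigma_e^2 I_n),

    estimated by residual maximum likelihood over the heritability
    h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

    Parameters
    ----------
    y : (n,) phenotype vector.
    X : (n, c) covariate matrix, or None for intercept only.  An intercept
        column is prepended unless one is already present
        (``add_intercept=False`` to suppress).
    genotypes : RawGenotypes, StandardizedGenotypes, or an (n, m) dosage
        array; standardized on construction with ``maf_min`` filtering.
    grm : precomputed (n, n) genomic relatedness matrix (alternative to
        genotypes; the first-order Monte Carlo route then unavailable).
    h2_bounds : search range for the heritability.
    """

    def __init__(self, y, X=None, genotypes=None, grm=None,
                 h2_bounds=(0.01, 0.99), maf_min: float = 0.01,
                 add_intercept: bool = True):
        self.y = np.asarray(y, dtype=float)
        n = self.y.shape[0]
        if X is None:
            X = np.ones((n, 1))
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[0] != n:
                raise ValueError("X and y have different numbers of samples")
            if add_intercept and not _has_intercept(X):
                X = np.column_stack([np.ones(n), X])
        self.X = X
        if (genotypes is None) == (grm is None):
            raise ValueError("provide exactly one of genotypes or grm")
        if genotypes is not None:
            if isinstance(genotypes, RawGenotypes):
                genotypes = standardize_genotypes(genotypes, maf_min=maf_min)
            elif not isinstance(genotypes, StandardizedGenotypes):
                raw = RawGenotypes(np.asarray(genotypes, dtype=float),
                                   list(range(n)), None)
                genotypes = standardize_genotypes(raw, maf_min=maf_min)
            if genotypes.n != n:
                raise ValueError("genotypes and y have different numbers of samples")
        else:
            grm = np.asarray(grm, dtype=float)
            if grm.shape != (n, n):
                raise ValueError("GRM shape does not match the phenotype")
        self.genotypes = genotypes
        self.grm = grm
        self.space = ParameterSpace(*h2_bounds)

    @classmethod
    def from_plink(cls, bfile: str, pheno: str, covar: str | None = None,
                   maf_min: float = 0.01, h2_bounds=(0.01, 0.99)) -> "HeritabilityModel":
        """Build a model from PLINK1 genotypes and GCTA-style text files."""
        raw = _io.read_plink(bfile)
        y, X, kept = _io.read_pheno_covar(pheno, covar, raw.sample_ids)
        sub = RawGenotypes(raw.dosages[kept], [raw.sample_ids[i] for i in kept],
                           raw.variant_ids)
        return cls(y, X, genotypes=sub, maf_min=maf_min,
                   h2_bounds=h2_bounds, add_intercept=False)

    @classmethod
    def from_gcta_grm(cls, grm_prefix: str, pheno: str, covar: str | None = None,
                      h2_bounds=(0.01, 0.99)) -> "HeritabilityModel":
        """Build a model from a precomputed GCTA binary GRM."""
        grm, ids = _io.read_gcta_grm(grm_prefix)
        y, X, kept = _io.read_pheno_covar(pheno, covar, ids)
        return cls(y, X, grm=grm[np.ix_(kept, kept)], h2_bounds=h2_bounds,
                   add_intercept=False)

    def fit(self, method: str = "sldf", n_rand: int = 15,
            lanczos_tol: float = 5e-5, opt_tol: float = 1e-5,
            max_iter: int | None = None, seed=0) -> REMLResults:
        """Estimate the variance components.

        method : "sldf" (derivative-free, accepts GRM or genotypes),
                 "fomc" (first-order Monte Carlo, genotypes required, also
                 returns BLUPs), or "exact" (dense deterministic reference,
                 small n only).
        """
        if method == "sldf":
            source = self.genotypes if self.genotypes is not None else self.grm
            return fit_sldf(self.y, self.X, source, self.space,
                            n_rand=n_rand, lanczos_tol=lanczos_tol,
                            opt_tol=opt_tol, max_iter=max_iter, seed=seed)
        if method == "fomc":
            if self.genotypes is None:
                raise ValueError("first-order Monte Carlo REML requires the "
                                 "genotype matrix, not a precomputed GRM")
            return fit_fomc(self.y, self.X, self.genotypes, self.space,
                            n_rand=n_rand, lanczos_tol=lanczos_tol,
                            opt_tol=opt_tol, max_iter=max_iter, seed=seed)
        if method == "exact":
            grm = self.grm if self.grm is not None else self.genotypes.grm()
            surf = dense_reml(self.y, self.X, grm,
                              h2_min=self.space.h2_min, h2_max=self.space.h2_max)
            flags = []
            if surf.unidentifiable:
                flags.append("unidentifiable")
            if surf.boundary:
                flags.append("boundary")
            return REMLResults(
                method="exact", h2=surf.h2_hat, sigma_g2=surf.sigma_g2,
                sigma_e2=surf.sigma_e2, loglik=surf.loglik_hat,
                n_eval=len(surf.h2_grid), lanczos_iters={},
                n=self.y.shape[0], c=self.X.shape[1],
                m=self.genotypes.m if self.genotypes is not None else None,
                n_rand=None, seed=None,
                h2_bounds=(self.space.h2_min, self.space.h2_max),
                converged=not surf.unidentifiable, flags=flags,
                _evaluator=surf.profile_loglik)
        raise ValueError(f"unknown method {method!r}")


def _has_intercept(X: np.ndarray) -> bool:
    return any(np.allclose(X[:, j], X[0, j]) and X[0, j] != 0
               for j in range(X.shape[1]))
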