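"""Linear-operator layer for the genomic variance-components model.

Provides genotype standardization, the genomic relatedness operator
``H_0 = (1/m) Z Z^T + tau_0 I`` in explicit-GRM or implicit-genotype form,
and the implicit covariate projector ``S = I - Q_X Q_X^T``.

The operator classes keep application counters so that the
overhead-vs-iteration accounting of the REML algorithms can be verified
empirically: every GRM action and every ``Z``/``Z^T`` product is counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RawGenotypes",
    "StandardizedGenotypes",
    "GenomicOperator",
    "ProjectedOperator",
    "Projector",
    "standardize_genotypes",
    "make_operator",
    "make_projector",
]


@dataclass
class RawGenotypes:
    """Hard-called allele dosages in {0, 1, 2}, NaN for missing.

    ``dosages`` is an ``(n, m)`` float array; ``sample_ids`` and
    ``variant_ids`` are parallel identifier sequences.
    """

    dosages: np.ndarray
    sample_ids: list
    variant_ids: list

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if m < 1:
            raise ValueError("need at least 1 variant")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


class StandardizedGenotypes:
    """Column-standardized genotype matrix Z with product counters.

    Each kept column j holds (g - 2 p_j) / sqrt(2 p_j (1 - p_j)) with p_j the
    sample allele frequency of the counted allele; missing dosages are
    mean-imputed, so they standardize to exactly zero.
    """

    def __init__(self, Z: np.ndarray, kept_index: np.ndarray, freqs: np.ndarray,
                 sample_ids=None, variant_ids=None):
        self.Z = np.asarray(Z, dtype=float)
        self.kept_index = np.asarray(kept_index, dtype=int)
        self.freqs = np.asarray(freqs, dtype=float)
        self.sample_ids = sample_ids
        self.variant_ids = variant_ids
        # counters for the per-iteration cost accounting
        self.n_z_products = 0
        self.n_zt_products = 0

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]

    def z_dot(self, v: np.ndarray) -> np.ndarray:
        """Z @ v, counting one product per column of v."""
        v = np.asarray(v)
        self.n_z_products += 1 if v.ndim == 1 else v.shape[1]
        return self.Z @ v

    def zt_dot(self, v: np.ndarray) -> np.ndarray:
        """Z.T @ v, counting one product per column of v."""
        v = np.asarray(v)
        self.n_zt_products += 1 if v.ndim == 1 else v.shape[1]
        return self.Z.T @ v

    def grm(self) -> np.ndarray:
        """Dense genomic relatedness matrix (1/m) Z Z^T (small-n use only)."""
        return (self.Z @ self.Z.T) / self.m


def standardize_genotypes(raw: RawGenotypes, maf_min: float = 0.0) -> StandardizedGenotypes:
    """Mean-impute, MAF-filter and standardize a dosage matrix.

    Columns that are monomorphic or whose minor allele frequency falls below
    ``maf_min`` are dropped; the surviving column index is recorded.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    G = raw.dosages
    n, m = G.shape
    n_obs = np.sum(~np.isnan(G), axis=0)
    col_sum = np.nansum(G, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, col_sum / np.maximum(n_obs, 1), np.nan) / 2.0
    # columns entirely missing give NaN frequency -> dropped
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
        keep = np.isfinite(p) & (p > 0.0) & (p < 1.0) & (maf >= maf_min)
    if not keep.any():
        raise ValueError("no variants remain after MAF/monomorphism filtering")
    kept = np.flatnonzero(keep)
    pk = p[kept]
    Gk = G[:, kept].copy()
    # mean imputation: missing entries become 2 p_j, hence exactly 0 after centering
    nan_mask = np.isnan(Gk)
    if nan_mask.any():
        Gk[nan_mask] = np.broadcast_to(2.0 * pk, Gk.shape)[nan_mask]
    Z = (Gk - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    variant_ids = None
    if raw.variant_ids is not None:
        variant_ids = [raw.variant_ids[j] for j in kept]
    return StandardizedGenotypes(Z, kept, pk, sample_ids=raw.sample_ids,
                                 variant_ids=variant_ids)


class GenomicOperator:
    """The SPD action v -> (1/m) Z Z^T v + tau0 v.

    ``mode`` is ``"implicit_genotype"`` (two matrix products per application,
    the GRM is never formed) or ``"explicit_grm"`` (one dense product).  The
    stored GRM never folds in ``tau0``; the shift is applied at application
    time so the same backing data serves every base shift.
    """

    def __init__(self, *, genotypes: StandardizedGenotypes | None = None,
                 grm: np.ndarray | None = None, tau0: float = 0.0):
        if tau0 < 0:
            raise ValueError("tau0 must be nonnegative")
        if (genotypes is None) == (grm is None):
            raise ValueError("provide exactly one of genotypes or grm")
        self.tau0 = float(tau0)
        self.n_apply = 0  # GRM-action count (per column)
        if genotypes is not None:
            self.mode = "implicit_genotype"
            self.genotypes = genotypes
            self.grm_matrix = None
            self.n = genotypes.n
        else:
            grm = np.asarray(grm, dtype=float)
            if grm.ndim != 2 or grm.shape[0] != grm.shape[1]:
                raise ValueError("explicit GRM must be square")
            if not np.allclose(grm, grm.T, atol=1e-8 * max(1.0, np.abs(grm).max())):
                raise ValueError("explicit GRM must be symmetric")
            self.mode = "explicit_grm"
            self.genotypes = None
            self.grm_matrix = grm
            self.n = grm.shape[0]

    def grm_action(self, v: np.ndarray) -> np.ndarray:
        """(1/m) Z Z^T v (or GRM @ v), without the tau0 shift."""
        v = np.asarray(v)
        self.n_apply += 1 if v.ndim == 1 else v.shape[1]
        if self.mode == "implicit_genotype":
            g = self.genotypes
            return g.z_dot(g.zt_dot(v)) / g.m
        return self.grm_matrix @ v

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.grm_action(v) + self.tau0 * v

    matmat = matvec


def make_operator(source, tau0: float = 0.0) -> GenomicOperator:
    """Build ``H_0`` from a StandardizedGenotypes or a dense GRM matrix."""
    if isinstance(source, StandardizedGenotypes):
        return GenomicOperator(genotypes=source, tau0=tau0)
    return GenomicOperator(grm=np.asarray(source), tau0=tau0)


@dataclass
class Projector:
    """Implicit orthogonal projector S: v -> v - Q_X (Q_X^T v)."""

    basis: np.ndarray  # (n, r) orthonormal covariate basis
    rank: int = field(init=False)

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float)
        self.rank = self.basis.shape[1]

    @property
    def n(self) -> int:
        return self.basis.shape[0]

    def apply(self, v: np.ndarray) -> np.ndarray:
        return v - self.basis @ (self.basis.T @ v)

    __call__ = apply

    def dense(self) -> np.ndarray:
        """Dense S = I - Q Q^T (small-n diagnostics only)."""
        return np.eye(self.n) - self.basis @ self.basis.T


def make_projector(X: np.ndarray) -> Projector:
    """Orthonormalize the covariate matrix and return the projector onto
    the orthogonal complement of its column space.

    Numerical rank deficiency is repaired by truncating the basis to the
    numerical rank (a warning is logged).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("covariate matrix must have at least one column")
    n, c = X.shape
    if n <= c:
        raise ValueError(f"need more samples than covariates (n={n}, c={c})")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(n, c) * np.finfo(float).eps if s.size else 0.0
    r = int(np.sum(s > tol))
    if r == 0:
        raise ValueError("covariate matrix is numerically zero")
    if r < c:
        logger.warning("covariate matrix is rank deficient: rank %d < %d columns; "
                       "basis truncated", r, c)
    return Projector(U[:, :r])


class ProjectedOperator:
    """The projected SPD action v -> S ((1/m) Z Z^T) S v + tau0 v.

    On the range of S this coincides with ``S H_0 S``; Krylov iterations
    seeded inside range(S) stay there, which is how the projected quadratic
    form and the first-order Monte Carlo operator are realized without ever
    forming K.
    """

    def __init__(self, base: GenomicOperator, projector: Projector):
        if base.n != projector.n:
            raise ValueError("operator and projector dimensions differ")
        self.base = base
        self.projector = projector
        self.n = base.n
        self.tau0 = base.tau0

    @property
    def n_apply(self) -> int:
        return self.base.n_apply

    def matvec(self, v: np.ndarray) -> np.ndarray:
        S = self.projector
        return S(self.base.grm_action(S(v))) + self.tau0 * v

    matmat = matvec
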