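"""Synthetic genotype/phenotype generator with known truth.

Simulates the generative model

    y = X beta + (1/sqrt(m)) Z u + e,   u ~ N(0, sigma_g^2 I_m),
                                        e ~ N(0, sigma_e^2 I_n),

with unlinked biallelic variants (dosages Binomial(2, p), p uniform over a
minor-allele-frequency window) and unrelated individuals.  There is no
linkage disequilibrium and no population structure by construction; the
generator exists to provide instances whose true variance components are
known exactly, so that estimator behaviour can be certified against the
dense oracle and against truth.

All randomness is driven by numpy SeedSequences; recorded seeds reproduce a
dataset bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomatrix import RawGenotypes, StandardizedGenotypes, standardize_genotypes

__all__ = ["PhenotypeDraw", "SyntheticDataset", "simulate_genotypes",
           "simulate_phenotype", "simulate_dataset"]


def simulate_genotypes(n: int, m: int, maf_low: float = 0.01,
                       maf_high: float = 0.49, seed=0,
                       missing_rate: float = 0.0) -> RawGenotypes:
    """Unlinked hard-called genotypes: p_j ~ U[maf_low, maf_high], dosages
    Binomial(2, p_j) i.i.d. across samples."""
    if not 0.0 < maf_low <= maf_high < 0.5:
        raise ValueError("need 0 < maf_low <= maf_high < 0.5")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=m)
    G = rng.binomial(2, p, size=(n, m)).astype(float)
    if missing_rate > 0.0:
        G[rng.random(size=G.shape) < missing_rate] = np.nan
    sample_ids = [f"S{i:06d}" for i in range(n)]
    variant_ids = [f"snp{j:06d}" for j in range(m)]
    return RawGenotypes(G, sample_ids, variant_ids)


@dataclass
class PhenotypeDraw:
    """One phenotype realization together with its latent variables."""

    y: np.ndarray
    u: np.ndarray          # latent standardized-SNP effects, length m
    e: np.ndarray          # residuals, length n
    sigma_g2: float
    sigma_e2: float
    h2: float


def simulate_phenotype(Z: StandardizedGenotypes | np.ndarray, X: np.ndarray,
                       beta: np.ndarray, h2: float, var_total: float = 1.0,
                       seed=0) -> PhenotypeDraw:
    """Draw y = X beta + (1/sqrt(m)) Z u + e at the stated heritability.

    ``sigma_g^2 = h2 * var_total`` and ``sigma_e^2 = (1 - h2) * var_total``;
    the latent u and e are returned for prediction-accuracy tests.  At the
    boundaries the corresponding latent vector is exactly zero.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    Zmat = Z.Z if isinstance(Z, StandardizedGenotypes) else np.asarray(Z, dtype=float)
    n, m = Zmat.shape
    rng = np.random.default_rng(seed)
    sigma_g2 = h2 * var_total
    sigma_e2 = (1.0 - h2) * var_total
    u = rng.standard_normal(m) * np.sqrt(sigma_g2)
    e = rng.standard_normal(n) * np.sqrt(sigma_e2)
    y = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float) \
        + Zmat @ u / np.sqrt(m) + e
    return PhenotypeDraw(y=y, u=u, e=e, sigma_g2=sigma_g2,
                         sigma_e2=sigma_e2, h2=h2)


@dataclass
class SyntheticDataset:
    """Complete simulated instance with its generative truth."""

    raw: RawGenotypes
    genotypes: StandardizedGenotypes
    X: np.ndarray
    beta: np.ndarray
    y: np.ndarray
    u: np.ndarray
    e: np.ndarray
    h2: float
    sigma_g2: float
    sigma_e2: float
    seed: object

    @property
    def n(self) -> int:
        return self.X.shape[0]


def simulate_dataset(n: int, m: int, h2: float, c: int = 3,
                     var_total: float = 1.0, maf_low: float = 0.01,
                     maf_high: float = 0.49, beta: np.ndarray | None = None,
                     seed=0) -> SyntheticDataset:
    """Genotypes + covariates (intercept first) + phenotype in one call.

    ``c`` counts all covariate columns including the intercept; the
    non-intercept columns are standard normal.  Default fixed effects are
    zero apart from a unit intercept.
    """
    if c < 1:
        raise ValueError("need at least the intercept covariate")
    root = np.random.SeedSequence(seed)
    s_geno, s_covar, s_pheno = root.spawn(3)
    raw = simulate_genotypes(n, m, maf_low, maf_high, seed=s_geno)
    geno = standardize_genotypes(raw, maf_min=0.0)
    rng = np.random.default_rng(s_covar)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(c - 1)])
    if beta is None:
        beta = np.zeros(c)
        beta[0] = 1.0
    draw = simulate_phenotype(geno, X, beta, h2, var_total, seed=s_pheno)
    return SyntheticDataset(raw=raw, genotypes=geno, X=X, beta=np.asarray(beta, float),
                            y=draw.y, u=draw.u, e=draw.e, h2=h2,
                            sigma_g2=draw.sigma_g2, sigma_e2=draw.sigma_e2,
                            seed=seed)
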