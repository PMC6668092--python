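# Methods

## Model and estimand

The package fits the two-variance-component genomic mixed model

    y = Xβ + (1/√m) Z u + e,   u ~ N(0, σ²g I_m),   e ~ N(0, σ²e I_n),

by residual maximum likelihood. With `K` an orthonormal basis of the
orthogonal complement of col X, the projected data satisfy
`Kᵀy ~ N(0, σ²g KᵀH_τK)` with `H_τ = (1/m)ZZᵀ + τI` and `τ = σ²e/σ²g`.
Profiling out the scale σ²g analytically (its stationarity value is
`σ̂²g(τ) = yᵀP_τy/(n−c)` with `P_τ = K(KᵀH_τK)⁻¹Kᵀ`) leaves a
one-dimensional criterion, maximized over `h² = 1/(1+τ)`:

    ℓ(h²) ∝ −(n−c)·ln(yᵀP_τy) − ln det(KᵀH_τK).

We work with this profiled form throughout; published presentations of the
criterion that mix `σ̂²g(τ)` and `σ̂²e(τ)` terms reduce to it (up to
constants) once the stationarity conditions are substituted, and the dense
reference optimizes the identical expression, so all cross-route
comparisons are estimand-identical. The constant `ln det(XᵀX)` is omitted
everywhere — it does not depend on τ.

## The shifted family

Given a heritability range [h²_min, h²_max], we anchor the base operator at
`τ₀ = (1−h²_max)/h²_max`, so every candidate τ in the range is
`H_τ = H₀ + σI` with σ = τ − τ₀ ≥ 0. Krylov subspaces are shift invariant,
so a Lanczos factorization `H₀U = UT` built once serves the whole family:
the k-step conjugate-gradient iterate of `(H₀+σI)x = b` is
`x_σ = ‖b‖·U(T+σI)⁻¹e₁`, O(nk) vector work and no operator applications.
Anchoring at the *upper* heritability bound also means every evaluated
`H_τ` is at least as well conditioned as `H₀`. Negative shifts are rejected
by design.

## Lanczos details

- **Full reorthogonalization.** Bases are stored anyway for the shifted
  solves, so each new direction is reorthogonalized against the whole
  stored basis (two classical Gram–Schmidt passes). Without this the
  quadrature weights degrade noticeably in finite precision. Cost is
  O(nk²) per seed, negligible at the problem sizes the stored-basis design
  targets (k ≪ n).
- **Convergence.** The conjugate-gradient residual norm of the seed system
  is computed per step from the tridiagonal system
  (`‖b‖·β_k·|(T_k⁻¹e₁)_k|`) and iteration stops when it falls below an
  absolute tolerance, default 5e−5. Hitting `max_iter`
  (default min(n, 1000)) flags the factorization but is not fatal.
- **Breakdown.** An off-diagonal β below 1e−13·‖b‖ means the Krylov
  subspace is invariant; the solve is then exact and termination is
  treated as convergence.
- **Block seeds.** Multiple right-hand sides are stepped jointly — one
  BLAS-3 operator application per iteration over the still-active columns,
  per-column coefficient updates — which is arithmetically identical to
  independent per-column runs (columns never interact). Convergence is the
  maximum per-column residual.
- **Shifted-residual predictor.** The scaled seed residual
  `δ/(δ+σ)·‖r‖` (δ the last diagonal Jacobi element) is exposed as a cheap
  convergence predictor. Empirically it is an upper bound — positive shifts
  only help, often making the shifted solve far more accurate than the
  bound suggests — and we verify exactly that: the σ=0 identity, the
  monotone decay in σ, and the bound direction, not equality.

## Stochastic Lanczos quadrature

`ln det(H₀+σI) = tr log(H₀+σI)` is estimated by Hutchinson probing with
`n_rand` normalized Rademacher vectors (entries ±1/√n, so
`E[vvᵀ] = I/n` and the estimator carries the prefactor `n/n_rand`).
For each probe, the Lanczos Jacobi matrix supplies a Gaussian quadrature
for the probe's spectral measure: nodes are the eigenvalues of T, and the
weight attached to node ℓ is the **squared** first component of
eigenvector ℓ. The squared form is forced by the Riemann–Stieltjes
construction (weights must be nonnegative and sum to one) and is confirmed
by the closed-form check `H₀ = cI`, where the quadrature must be exact;
an unsquared convention fails that check immediately. A shift simply
translates the nodes, so the entire σ-family of log-determinants comes from
one set of factorizations. `n_rand` defaults to 15.

The SLQ probe stream, the first-order Monte Carlo stream, and the
simulator's streams are all seeded independently through numpy
`SeedSequence` spawning, so no two consumers share randomness.

## The derivative-free route (SLDF)

One overhead round builds: (i) factorizations of `H₀` seeded with the
`n_rand` probes and the `c` covariate columns (one block call), and (ii) a
factorization of the projected operator seeded with `Sy`, where
`S = I − Q_X Q_Xᵀ` is the implicit covariate projector from the economy
orthogonal factorization of X (numerical rank deficiency truncates the
basis with a logged warning). The criterion at any h² is then assembled
from three pieces, all vector work:

- `yᵀP_τy = (Sy)ᵀ(SH₀S + σI)⁻¹(Sy)`, valid because the pseudoinverse of
  the projected operator restricted to range(S) coincides with the shifted
  inverse there — the seed lies in range(S) and the iteration never leaves
  it, so K is never formed;
- `ln det(H_τ)` by SLQ at shift σ;
- `ln det(XᵀH_τ⁻¹X)` from the c stored covariate solves and a c×c Cholesky
  (this three-term split of `ln det(KᵀH_τK)` is the standard equivalent
  formulation; the dropped third term is the `ln det(XᵀX)` constant).

Brent's bounded method maximizes ℓ over [h²_min, h²_max] with absolute
h²-tolerance 1e−5 (default), at most 100 evaluations. An optimum within
10× the tolerance of either bound is flagged `boundary`. Before
optimization a five-point scan checks for a flat criterion (spread below
1e−6): an identity-GRM instance is *exactly* flat in the profiled
criterion — τ and σ²g are confounded — and is flagged `unidentifiable`.

## The first-order Monte Carlo route (FOMC)

The REML stationarity conditions equate `ũᵀũ` and `ẽᵀẽ` — squared norms of
the BLUPs `ũ(τ) = m^{−1/2}ZᵀSH́_τ⁻¹Sy`, `ẽ(τ) = τH́_τ⁻¹Sy` with
`H́_τ = (1/m)SZZᵀS + τI` — with their conditional expectations. The
expectations are estimated by Monte Carlo over synthetic projected
phenotypes, and the scale-free statistic

    f_r(τ) = ln[(ũᵀũ)/(ẽᵀẽ)] − ln[E_MC(ũᵀũ)/E_MC(ẽᵀẽ)]

is driven to zero by bracketed root-finding (Brent) on the h² scale,
tolerance 1e−5. If f_r does not change sign over the bracket the fit
returns the endpoint with the smaller |f_r|, flagged.

Two design points matter for correctness:

- **MC phenotypes must track τ.** Each sample keeps its genetic part
  `a_k = m^{−1/2}SZǔ_k` and residual part `ě_k = Sg_k` (`ǔ_k, g_k`
  standard normal; S idempotent gives Cov(ě) = S) as *separate* Lanczos
  seed systems, and the phenotype used at variance ratio τ is
  `y̌_k(τ) = a_k + √τ·ě_k`, whose covariance on range(S) is exactly `H́_τ`
  at unit genetic scale (the scale cancels in the ratio). Assembling the
  solve as `H́_τ⁻¹y̌_k(τ) = solve(a_k) + √τ·solve(ě_k)` keeps the
  per-iteration cost at two stored-basis combinations per sample. This is
  why the overhead round factorizes 2·n_rand + 1 seed systems. Freezing
  `y̌_k` at unit variances instead (covariance `H́₁` regardless of τ)
  biases the root severely — on a test instance the frozen-sample
  population root sat at h² ≈ 0.91 against a true REML optimum of 0.44,
  while the τ-tracking form zeroes f_r at the optimum to 1e−8.
- **Consistent norms.** `E_MC(ũᵀũ)` is the plain sample mean of
  `‖m^{−1/2}ZᵀS H́_τ⁻¹S y̌_k(τ)‖²` — the same functional applied to the MC
  phenotypes as to the observed one — so both logs in f_r compare
  like-with-like quantities (an inconsistent prefactor would shift the
  root by a constant).

After the overhead round each f_r evaluation performs zero applications of
`H́` and exactly one `Zᵀ·vector` product per BLUP right-hand side
(observed phenotype plus n_rand samples) — the one unavoidable O(mn)
per-iteration cost, which is also what makes this route require genotypes
rather than a precomputed GRM. At the root, variance components are
profiled from the quadratic form re-using the phenotype factorization
(σ̂²g = yᵀP_τ̂y/(n−c), σ̂²e = τ̂σ̂²g), keeping result semantics identical
across algorithms, and the BLUPs at τ̂ are returned for free.

## Dense reference

`dense_reml` eigendecomposes `KᵀGRM·K` once (explicit complete orthogonal
K), evaluates the exact profiled criterion on a 64-point h² grid, and
refines the argmax by bounded scalar minimization to 1e−8. A grid spread
below 1e−9 flags the surface unidentifiable; an argmax within 1e−6 of a
bound flags it boundary. The reference is validated only by closed forms
and invariances (scalar matrices, permutation equivariance, boundary
behaviour) — it is the root of the trust chain and deliberately contains
no Krylov machinery.

## Genotype conventions

Standardization divides centered dosages by `√(2p(1−p))` at the sample
allele frequency — the binomial variance under Hardy–Weinberg, the
standard GRM convention — rather than the sample standard deviation;
column variance is therefore only approximately one and tests assert the
centering, not the scale. Missing dosages are mean-imputed before
centering (they standardize to exactly zero). Monomorphic columns and
columns below the minor-allele-frequency cutoff (default 1%) are dropped,
and the GRM divisor m is the number of *kept* columns. Allele orientation
only flips column signs and is ignored. The explicit-GRM operator stores
the matrix without the base shift folded in, so one stored GRM serves any
parameter range.

## Synthetic data

The generator draws allele frequencies uniform on [0.01, 0.49] (mirroring
a 1% MAF cutoff), dosages Binomial(2, p) independently across samples and
markers, covariates standard normal plus an intercept (fixed effects zero
except a unit intercept), and phenotypes from the generative model at the
stated h² with total variance 1. It emulates *unrelated* individuals and
*unlinked* markers only: no linkage disequilibrium, no population
structure, no ascertainment, no case–control liability scale. Passing
recovery tests therefore certify the estimators under the model's own
assumptions — they say nothing about confounding robustness on real
cohorts, which is out of scope here.

## Test and acceptance problem sizes

Oracle-agreement and recovery checks run at n between 120 and 1000 with
m = 2n, 10–20 replicates per condition, and n_rand of 15–100 depending on
the check — sizes chosen so dense eigendecomposition references remain
cheap while Monte Carlo error bars are tight enough to be informative.
Stochastic-vs-oracle agreement is asserted on means over replicates with
3-standard-error bands; at n = 1000 the SLQ-induced argmax noise in the
derivative-free route has standard deviation near 0.008 on the h² scale
(it shrinks like (n·n_rand)^{−1/2}, so it is an order of magnitude smaller
at biobank n), and the per-replicate agreement bound reflects that.

## Known limitations

- Two variance components only; the shift-invariance trick does not extend
  to three or more simultaneous covariance structures.
- No standard errors for ĥ² (no Hessian/average-information machinery).
- Stored bases cost O(n·k) memory per seed system; a two-pass basis-free
  mode is deliberately out of scope.
- In-memory genotypes only; no out-of-core or dosage formats.
- `f_r` monotonicity in τ is an empirical observation on the synthetic
  instances (increasing, in our sign convention), not a theorem; the root
  finder only requires a sign change.
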