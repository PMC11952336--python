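# Methods

This note documents the models implemented in `gplandscape`, the numerical
choices behind them, what the synthetic data generators emulate, and the
limitations a user should keep in mind.

## Sequence spaces and structured operators

A space is defined by an ordered alphabet per site; genotypes are indexed
mixed-radix (site 0 most significant), so a complete landscape is a plain
vector of length `n = Π_p α_p`. All structured matrices are applied
matrix-free through their Kronecker factorizations over sites:

* **Graph Laplacian.** `L = Σ_p I ⊗ … ⊗ (α_p I − J) ⊗ … ⊗ I` (J = all-ones).
  On uniform-α spaces its eigenspaces are the interaction-order subspaces,
  with eigenvalue `αk` at order `k`.
* **Projections.** `P_U = ⊗_p F_p` with `F_p = I − J/α_p` on sites in `U`
  and `J/α_p` elsewhere; `P_k = Σ_{|U|=k} P_U`. Rather than summing
  `C(ℓ,k)` Kronecker terms, all order components are computed in one
  `O(ℓ²n)` sweep using the generating identity
  `⊗_p (J/α_p + z(I − J/α_p)) = Σ_k z^k P_k`: a dynamic program over sites
  maintains the vector coefficients of the polynomial in `z`. This uses
  only per-site averages and differences, so it is numerically stable and
  valid for mixed alphabets.
* **Distance kernels.** Any matrix whose entries depend only on Hamming
  distance (uniform α) is diagonal in the order basis; its eigenvalues are
  the Krawtchouk transform of the distance profile. We apply such kernels
  in this spectral form, `Av = Σ_k μ_k P_k v`. The equivalent
  polynomial-in-`L` representation (coefficients from Newton divided
  differences through the nodes `αk`) is also provided; the spectral route
  is used internally because high powers of `L` lose relative precision by
  roughly the condition of the Vandermonde system, while the spectral sweep
  does not. Both routes are cross-checked in the tests.
* **Epistasis operator.** `Δ(P) = Σ_{|V|=P} ⊗_p (α_p I − J if p∈V else I)`.
  Since `gᵀ(αI − J)g = Σ_{a<b}(g_a − g_b)²` on one site, the quadratic form
  `fᵀΔ(P)f` enumerates every local P-way epistatic coefficient (P-th finite
  difference over a subcube) across all site subsets, allele pairs and
  backgrounds. The coefficient count is
  `s = Σ_{|V|=P} Π_{p∈V} C(α_p,2) · Π_{p∉V} α_p`, and brute-force
  enumeration is the normative oracle in the test suite. Applying `Δ(P)`
  costs `C(ℓ,P)` Kronecker terms; this is the scaling bottleneck for large
  `P` but is immaterial for the default `P = 2`.

Dense materializations exist only as test oracles and refuse to build
operators beyond 4096 genotypes.

## Variance decomposition conventions

"Variance" is the population variance over the uniform distribution on
genotypes (divide by `n`), which makes Parseval exact:
`mean(f²) = Σ_U ‖f_U‖²/n`, with the order-0 term equal to the squared mean
and excluded from variance totals. Percent-of-variance outputs are over
orders `k ≥ 1`. Per-site and per-pair profiles sum subset variances over
`U ∋ p` and `U ⊇ {p,q}`; the pair matrix stores `|U| = 2` in the lower
triangle and `|U| > 2` in the upper. Because the normalization of per-order
heatmaps is a presentation choice, both per-order and total-variance
normalizations can be derived from the emitted absolute values.

## Gaussian-process inference

**Priors.** The `Δ(P)` family is improper: precision `(a/s)Δ(P)` penalizes
the mean squared local order-P coefficient and leaves lower orders flat.
The VC family is proper on orders `k ≥ 1`: `K = Σ_k λ_k K_k` with `K_k`
normalized to unit diagonal, so `λ_k` is the per-genotype prior variance of
the order-k component and the prior covariance at distance `d` is
`Σ_k λ_k b_k(d)` with `b_k` the normalized Krawtchouk profile. The global
mean is treated as an improper flat prior: data are centered before fitting
and the mean is restored afterwards (`λ_0 = 0` by convention). A
consequence is that contrast variances do not include uncertainty in the
global mean; shift-invariant contrasts (mutational effects, epistatic
coefficients) are unaffected. A strict zero-mean treatment is available via
`center=False`.

**Posteriors.** Covariance form (VC):
`f̂ = ȳ + K_{·x}(K_xx + D_σ²)^{-1}(y − ȳ)`; posterior covariance queries use
`wᵀΣw′ = wᵀKw′ − (EKw)ᵀ(K_xx + D)^{-1}(EKw′)`, one linear solve per
contrast. When the number of observations is at most 3000 the system is
Cholesky-factored once (distances between observed sequences are cheap to
enumerate) and all queries reuse the factor; otherwise solves run through
conjugate gradients on the matrix-free operator. A diagonal jitter of
`1e-10·K(0)` guards exact-interpolation cases where `K_xx` is singular.
Precision form (`Δ(P)` priors): CG on `(a/s)Δ(P) + E D_{1/σ²} Eᵀ`; if the
observations do not identify the unpenalized low-order subspace the solver
reports non-convergence with that explanation. CG uses relative tolerance
1e-8 and `max(200, 10√n)` iterations; preconditioning is an identity hook.

**MEI.** With exact observations, the unobserved block solves
`Δ_uu f_u = −Δ_uo y` by CG (the Schur complement of the constraint), which
minimizes `fᵀΔ(P)f` subject to the data and is independent of `a`; with
noise it is MAP inference under the `Δ(P)` prior.

**Kernel alignment.** The empirical distance covariance uses all observed
pairs per distance; `cov(0)` is the sample variance minus the mean known
noise variance (the only distance affected by independent errors), and
covariances at `d > 0` are used raw. For complete data the whole profile is
computed exactly from one order-component sweep
(`fᵀA_d f = Σ_k K_d(k)‖f_k‖²`) instead of `O(n²)` pair enumeration.
Components are fitted by nonnegative least squares weighted by pair counts.
Being a plug-in estimate, the fitted `λ` inherits sampling noise: on a
single realized landscape the realized per-order variances are
`λ_k·χ²_{m_k}/m_k` (`m_k` = subspace dimension), so recovery of *planted*
values is assessed on replicate averages, and downstream credible intervals
can be mildly over- or under-confident when the high-order tail is
misestimated from sparse data (coverage of nominal 95% intervals typically
lands between 90 and 96% across simulation seeds in our checks).

**SeqDEFT.** The MAP problem
`min (a/2s)φᵀΔ(P)φ + Nᵀφ + N_T·logΣe^{−φ}` is convex and solved by L-BFGS
with matrix-free gradients, warm-started at the `a = ∞` fit and, along a
grid, at the previous solution. The `a = ∞` limit optimizes over the
order-`< P` subspace by projecting iterates (initialized at the closed-form
product-of-marginals model when `P = 2`); `a = 0` is the empirical
distribution. `φ` is gauge-fixed so `Σe^{−φ} = 1`. The grid default is 20
geometric points spanning six orders of magnitude centered on `s/N_T`, plus
both limits; cross-validation scatters the `N_T` individual draws into 5
seeded folds and scores held-out multinomial log-likelihood, and the final
model is refitted on all data at the selected `a*`. The Laplace posterior
uses the Hessian `(a/s)Δ(P) + N_T(diag(π̂) − π̂π̂ᵀ)`, whose null space is the
additive constant in `φ`; covariance queries therefore require weights
summing to zero and are solved by CG with the constant projected out.

## Evolutionary embedding

Rates use the origin-fixation form `Q(i,j) = M(i,j)·S/(1−e^{−S})` with
`S = c(f(j) − f(i))`: the factor tends to 1 as `S → 0`, exceeds 1 for
beneficial substitutions, and decays like `|S|e^{S}` for deleterious ones —
evaluated branch-wise with `expm1` on both tails for stability. Mutation
models are per-site rate matrices (default: rate 1 between all alleles,
i.e. time in units of the inverse mutation rate); each site model must be
time-reversible, which is verified against its stationary distribution at
construction. The chain is then reversible with
`π(i) ∝ π_M(i)e^{cf(i)}`.

The selection scale `c` is chosen either as `c = 1` for log-probability
landscapes (the stationary distribution then reproduces the modeled
probabilities exactly) or by root-finding the value whose stationary mean
phenotype hits a user target (the mean is monotone in `c`).

Embedding solves the symmetrized eigenproblem `D_π^{1/2}QD_π^{-1/2}`
(dense `eigh` up to 2048 states, Lanczos `eigsh` above), back-transforms to
right eigenvectors normalized to `r_kᵀD_πr_k = 1`, and rescales to
`u_k = r_k/√(−λ_k)`. This normalization is pinned by the commute-time
identity — with the full spectrum,
`Σ_k (u_k(i) − u_k(j))² = H(i,j) + H(j,i)` exactly — which the tests verify
against hitting times from dense linear solves on every model up to 64
states. Axis signs are fixed by nonnegative π-weighted skewness so layouts
are reproducible. Default 10 axes; the relaxation-time table reports up to
the top 20.

## Shine-Dalgarno thermodynamic model

The expected log signal of a 9-nt variable sequence is
`μ_x = log(β₀ + Σ_p exp(−(θ₀ + Σ_{i,c} x_p(i,c)ΔΔG_ic)/RT))` over all nine
fully contained 8-mer windows of the flank-extended sequence
(CCG + variable 9-mer + UGAG), assuming binding-limited initiation, low
occupancy, and at most one bound register at a time. `RT = 1.9872e-3 ×
310 = 0.6160` kcal/mol. Each `ΔΔG` row is constrained to sum to zero; the
gauge freedom between row offsets and `θ₀` is removed by optimizing a raw
matrix that is row-centered in the forward pass. `θ₀` is a single composite
offset (mean binding energy plus the bound-state rate scale); only the
composite is identified by the likelihood. `β₀` and the extra variance `σ²`
are optimized on the log scale to stay positive. Fitting uses Adam
(learning rate 0.02, 1500 iterations) with analytic gradients that are
finite-difference-checked in the tests; all exponentials are evaluated as
`exp(logB − μ)` so no overflow occurs for any parameter values.
Windows are required to lie fully inside the extended sequence. The
4-parameter calibration model for externally supplied ensemble energies
(`μ = log(β₀ + e^{θ₀+θΔG})`) is fitted the same way; no folding software is
invoked — the energy table is an input.

## Synthetic data generators

The fixture module emulates the package's three study designs at desk
scale:

* `vc_landscape`: a landscape drawn from a VC prior with geometrically
  decaying per-order variances (factor 0.5, total variance 1), observed
  with measurement variance 0.058 (a typical replicate-pooled MAVE error),
  2% missing genotypes, and a 0.1% held-out test split. Default 5 DNA
  sites (1024 genotypes).
* `seqdeft_counts`: a latent field drawn from the order-2 epistasis prior,
  exponentiated to a probability distribution and sampled multinomially
  (default 5000 draws over 256 genotypes) — a genome-scale motif collection
  in miniature.
* `thermo_mave`: log-signal measurements from the binding model with a
  strong consensus motif (per-position depth 0.46 kcal/mol plus seeded
  variation, background 0.47, measurement sd 0.1 at n = 5000).

These generators capture the sampling noise, missingness and dynamic ranges
of the real designs but not their systematic artifacts: no global
measurement nonlinearity, no phylogenetic correlation between natural
sequences (draws are i.i.d.), and no sequence-composition biases in
coverage. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative assumptions, not robustness to those
real-data violations.

## Numerical choices and degenerate inputs

* CG: relative residual 1e-8, `max(200, 10√n)` iterations; failures raise
  with the residual rather than returning silently.
* SeqDEFT L-BFGS: objective scaled by `1/N_T`, gradient tolerance 1e-9,
  convergence re-checked on the returned gradient norm.
* Constant observations make the distance correlation undefined; the table
  flags this with NaNs instead of dividing by zero.
* Posterior variances are clipped at zero against roundoff.
* Landscapes must be finite and complete; incomplete CSVs and unknown
  symbols fail with the offending site/row named.
* Problem sizes in tests and the acceptance script (spaces up to 4096
  genotypes, 2000-observation regressions, 5000-draw count data, 100
  replicate averages for estimator-bias checks) were chosen so every
  statistical check has comfortable resolution while the whole suite runs
  in a few minutes on one core.

## Known limitations

* Everything stores at least a handful of length-`n` vectors, so sequence
  length is bounded in practice (~12 nucleotides / ~5 amino acids / ~24
  biallelic sites on ordinary memory).
* MEI and VC regression are phenomenological: global nonlinearities of the
  measurement process are absorbed into apparent epistasis rather than
  modeled.
* SeqDEFT treats observed sequences as independent draws; correlated
  (phylogenetically related) collections violate this.
* Exhaustive subset-variance enumeration is exponential in `ℓ` and is
  guarded at 16 sites; targeted subset lists remain available beyond that.
* The VC credible intervals are empirical-Bayes plug-in intervals; they do
  not propagate uncertainty in the fitted `λ` (see above).
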