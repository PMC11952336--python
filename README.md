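# gplandscape

Inference, decomposition and visualization of **complete genotype-phenotype
maps** over combinatorial sequence spaces — up to millions of genotypes —
using matrix-free Gaussian-process models.

## Who this is for

A genotype-phenotype map assigns a scalar phenotype `f(x)` to every sequence
`x` of length `ℓ` over per-site alphabets (α alleles per site, possibly
site-specific). Two kinds of data constrain such maps at scale:

* **MAVE data** (multiplex assays of variant effects): measurements `y` with
  known Gaussian noise variance for a subset of sequences;
* **natural sequence collections**: counts `N_i` of how often each sequence
  occurs, e.g. a regulatory motif across a genome, modeled multinomially.

`gplandscape` turns either into a posterior distribution over the *complete*
vector `f` (all `α^ℓ` genotypes), quantifies the epistasis it contains, and
embeds it for visualization — without ever materializing an `α^ℓ × α^ℓ`
matrix.

## Core models

All priors and structured matrices live on the Hamming graph (nodes =
genotypes, edges = point mutations) and are applied as Kronecker-factored
linear operators:

* **Minimum epistasis interpolation (MEI).** Complete the landscape by
  minimizing the mean squared local epistatic coefficient
  `ε̄² = (1/s) fᵀΔ(P)f` subject to the observations (equivalently, MAP
  inference under the improper prior with precision `(a/s)Δ(P)`, which
  leaves interactions of order `< P` unpenalized).
* **Variance-component (VC) regression.** Gaussian-process regression with
  prior covariance `K = Σ_k λ_k K_k`, where `λ_k` is the prior variance
  carried by order-`k` interactions. The `λ_k` are fitted by *kernel
  alignment*: nonnegative weighted least squares of the prior's
  distance-covariance function against the empirical one — an
  `(ℓ+1)`-dimensional problem regardless of data size.
* **SeqDEFT.** Density estimation over sequence space: `π_i ∝ exp(−φ_i)`
  with the same `Δ(P)` penalty on the latent field `φ` and a multinomial
  likelihood; the prior strength `a` is chosen by cross-validated held-out
  log-likelihood between the two limit models (`a→0`: empirical
  frequencies; `a=∞`: the independent-sites model for `P = 2`).
* **Epistasis decomposition.** `f = Σ_k f_k = Σ_U f_U` via the orthogonal
  projections `P_k` (interaction order) and `P_U` (site subset), giving
  variance-by-order, per-site-by-order and per-pair summaries, plus `ε̄²`.
* **Evolutionary embedding.** A weak-mutation Markov chain with rates
  `Q(i,j) = M(i,j)·S/(1−e^{−S})`, `S = c(f(j)−f(i))`, stationary
  distribution `π(i) ∝ π_M(i)e^{cf(i)}`. Diffusion axes are rescaled
  subdominant eigenvectors `u_k = r_k/√(−λ_k)`, so squared embedding
  distances approximate commute times; `−1/λ_k` are relaxation times.
* **Shine-Dalgarno thermodynamic model.** A 27-parameter biophysical model
  of translation initiation: additive, register-independent binding
  energies of the anti-SD tail over all 8-mer windows of the flanked
  variable region, with background fluorescence and a Gaussian log-scale
  likelihood, fitted by maximum likelihood (Adam, analytic gradients).

## Worked example

```python
import numpy as np
import gplandscape as gl

rng = np.random.default_rng(0)
space = gl.SequenceSpace(["ACGT"] * 5)                    # 1024 genotypes
truth = gl.sample_prior(space, gl.VCPrior((0, 1.0, 0.5, 0.2, 0.1, 0.05)), rng)
obs = gl.simulate_observations(truth, 0.24, 0.3, rng)     # noise sd, 30% missing

prior = gl.fit_variance_components(obs)                   # kernel alignment
post = gl.vc_regression(obs, prior)                       # full posterior

r2 = 1 - np.mean((post.mean - truth.values) ** 2) / truth.variance
eps2, rms = gl.mean_squared_epistatic_coefficient(post.to_landscape(), 2)
dec = gl.variance_components(post.to_landscape())

c = gl.calibrate_c(post.to_landscape(),
                   target_mean=float(np.quantile(post.mean, 0.9)))
emb = gl.embed(gl.build_rate_matrix(post.to_landscape(), c), n_axes=3)
```

Output:

```
fitted variance components: [0.    0.976 0.674 0.175 0.078 0.022]
R^2 of posterior mean vs truth: 0.921
mean squared epistatic coefficient: 1.021 (rms 1.011)
percent variance by order: [53.3 35.6  8.   2.5  0.5]
selection scale c = 1.15; relaxation times: [0.588 0.554 0.478]
```

Reading this: kernel alignment recovers a decaying variance profile close to
the simulated one; the reconstructed map explains 92% of the true variance
despite 30% missing data and measurement noise; about half of the
landscape's variance is additive and a third pairwise, with a measurable
higher-order tail; and after calibrating the selection scale so the
stationary mean phenotype sits at the 90th percentile, the three leading
diffusion axes decay on comparable timescales (no single dominant fitness
barrier in this random landscape).

The same steps are available from the shell:

```bash
gplandscape simulate vc_landscape --out sim --seed 1 --l 5
gplandscape fit-vc --train sim/train.csv --out fit
gplandscape decompose --landscape fit/landscape.csv --out dec
gplandscape embed --landscape fit/landscape.csv --out emb --axes 3 --c-target 1.0
```

plus `fit-mei`, `fit-seqdeft`, `contrast` and `fit-thermo`.

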