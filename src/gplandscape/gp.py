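"""Gaussian-process inference of complete genotype-phenotype maps.

Two prior families over landscapes ``f`` on a sequence space:

* ``DeltaPrior(P, a)`` — improper Gaussian with precision ``(a/s) Delta(P)``;
  it penalizes the mean squared local P-way epistatic coefficient and leaves
  interactions of order ``< P`` unconstrained.  Minimum epistasis
  interpolation (MEI) is the noiseless limit of MAP inference under it.
* ``VCPrior(lambdas)`` — covariance ``K = sum_k lambda_k K_k`` where ``K_k``
  is the order-k kernel normalized to unit diagonal, so ``lambda_k`` is the
  prior per-genotype variance carried by order-k interactions.  The
  hyperparameters are fitted by kernel alignment: weighted least squares of
  the prior distance-covariance function against the empirical one.

Observations come with known Gaussian noise; posteriors are Gaussian with
matrix-free means and a covariance exposed through ``cov_query`` (one linear
solve per requested contrast).  A direct Cholesky path is used when the
number of observations is small enough to factor; otherwise everything runs
through conjugate gradients on structured operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import nnls

from .linop import (ConvergenceError, LinearMap, cg_solve, delta_operator,
                    distance_profile_eigenvalues, epistatic_coefficient_count,
                    krawtchouk_matrix, operator_from_order_eigenvalues,
                    order_components)
from .space import Landscape, SequenceSpace

__all__ = [
    "GaussianObservations",
    "CountData",
    "DeltaPrior",
    "VCPrior",
    "PosteriorGaussian",
    "gaussian_posterior",
    "mei",
    "empirical_distance_correlation",
    "fit_variance_components",
    "vc_regression",
    "posterior_contrast",
    "expand_pattern",
    "mutation_contrast_weights",
    "sample_prior",
    "simulate_observations",
    "simulate_counts",
]

DIRECT_SOLVE_MAX_OBS = 3000


# ---------------------------------------------------------------------------
# Data modalities
# ---------------------------------------------------------------------------

@dataclass
class GaussianObservations:
    """Phenotype measurements with known per-observation noise variance."""

    space: SequenceSpace
    obs_indices: np.ndarray
    y: np.ndarray
    noise_var: np.ndarray

    def __post_init__(self):
        self.obs_indices = np.asarray(self.obs_indices, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=float)
        nv = np.asarray(self.noise_var, dtype=float)
        if nv.ndim == 0:
            nv = np.full(len(self.y), float(nv))
        self.noise_var = nv
        n = self.space.n_genotypes
        if self.obs_indices.size == 0:
            raise ValueError("no observations")
        if self.obs_indices.min() < 0 or self.obs_indices.max() >= n:
            raise ValueError("observation index out of range")
        if len(np.unique(self.obs_indices)) != len(self.obs_indices):
            raise ValueError("observation indices must be unique")
        if not (len(self.y) == len(self.obs_indices) == len(self.noise_var)):
            raise ValueError("obs_indices, y and noise_var must have equal length")
        if np.any(self.noise_var < 0):
            raise ValueError("noise variances must be >= 0")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def is_complete(self) -> bool:
        return self.n_obs == self.space.n_genotypes


@dataclass
class CountData:
    """Observed counts per genotype (e.g. from a natural-sequence collection)."""

    space: SequenceSpace
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.space.n_genotypes,):
            raise ValueError("counts must have one entry per genotype")
        if np.any(self.counts < 0) or not np.all(self.counts == self.counts.astype(int)):
            raise ValueError("counts must be nonnegative integers")
        self.counts = self.counts.astype(np.int64)
        if self.n_total < 1:
            raise ValueError("need at least one observation (N_T >= 1)")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_total


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaPrior:
    """Improper Gaussian prior with precision ``(a/s) Delta(P)``.

    Larger ``a`` shrinks local order-P epistatic coefficients harder;
    ``a = inf`` forces them to zero (interactions of order ``< P`` are never
    penalized).
    """

    P: int = 2
    a: float = 1.0

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("a must be >= 0")
        if self.P < 1:
            raise ValueError("P must be >= 1")

    def coefficient_count(self, space: SequenceSpace) -> int:
        return epistatic_coefficient_count(space, self.P)

    def precision_operator(self, space: SequenceSpace) -> LinearMap:
        scale = self.a / self.coefficient_count(space)
        return scale * delta_operator(space, self.P)


@dataclass(frozen=True)
class VCPrior:
    """Variance-component prior: ``K = sum_k lambda_k K_k`` with unit-diagonal K_k.

    ``lambdas[k]`` is the prior variance contributed by order-k interactions
    per genotype; the implied distance-covariance function is
    ``K(d) = sum_k lambda_k b_k(d)`` with ``b_k`` the normalized Krawtchouk
    profile of ``P_k``.  ``lambdas[0]`` is conventionally 0: the global mean
    is handled as an improper flat prior by centering the data.
    """

    lambdas: tuple[float, ...]

    def __init__(self, lambdas):
        lam = tuple(float(x) for x in lambdas)
        if any(x < 0 for x in lam):
            raise ValueError("variance components must be >= 0")
        object.__setattr__(self, "lambdas", lam)

    def _check(self, space: SequenceSpace) -> np.ndarray:
        lam = np.asarray(self.lambdas)
        if lam.shape != (space.length + 1,):
            raise ValueError(
                f"need {space.length + 1} variance components, got {lam.shape}"
            )
        if not space.is_uniform:
            raise ValueError("VC priors require uniform alphabet sizes")
        return lam

    def kernel_eigenvalues(self, space: SequenceSpace) -> np.ndarray:
        """Eigenvalue of K on each order subspace: ``lambda_k n / m_k``."""
        lam = self._check(space)
        ell, alpha = space.length, space.alpha
        m = np.array([comb(ell, k) * (alpha - 1) ** k for k in range(ell + 1)],
                     dtype=float)
        return lam * space.n_genotypes / m

    def kernel_operator(self, space: SequenceSpace) -> LinearMap:
        return operator_from_order_eigenvalues(space,
                                               self.kernel_eigenvalues(space))

    def covariance_by_distance(self, space: SequenceSpace) -> np.ndarray:
        """Prior covariance between genotypes at each Hamming distance."""
        lam = self._check(space)
        B = order_distance_basis(space)  # (ell+1 distances, ell+1 orders)
        return B @ lam


def order_distance_basis(space: SequenceSpace) -> np.ndarray:
    """Matrix ``B[d, k] = b_k(d)``: normalized covariance profile of order k.

    ``b_k(d) = K_k(d) / K_k(0)`` (Krawtchouk), the correlation at distance d
    of a pure order-k landscape; ``b_k(0) = 1``.
    """
    if not space.is_uniform:
        raise ValueError("distance basis requires uniform alphabet sizes")
    W = krawtchouk_matrix(space.length, space.alpha)
    return (W / W[:, [0]]).T


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorGaussian:
    """Gaussian posterior over a complete landscape.

    ``mean`` is the full posterior mean vector; ``cov_query(w, w2)`` returns
    ``w' Sigma w2`` by solving one linear system per weight vector, and
    ``variances(indices)`` batches the per-genotype marginals.
    """

    space: SequenceSpace
    mean: np.ndarray
    _cov_quad: object = field(repr=False, default=None)
    _var_batch: object = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict)

    def cov_query(self, w: np.ndarray, w2: np.ndarray | None = None) -> float:
        if self._cov_quad is None:
            raise ValueError("this posterior does not expose a covariance")
        return float(self._cov_quad(np.asarray(w, float),
                                    np.asarray(w2, float) if w2 is not None else None))

    def variances(self, indices) -> np.ndarray:
        idx = np.asarray(indices, dtype=np.int64)
        if self._var_batch is not None:
            return self._var_batch(idx)
        out = np.empty(idx.size)
        e = np.zeros(self.space.n_genotypes)
        for j, i in enumerate(idx):
            e[i] = 1.0
            out[j] = self.cov_query(e)
            e[i] = 0.0
        return out

    def to_landscape(self, label: str = "posterior mean") -> Landscape:
        return Landscape(self.space, self.mean, label=label)


# ---------------------------------------------------------------------------
# Gaussian posteriors under the two prior forms
# ---------------------------------------------------------------------------

def _pairwise_distances(space: SequenceSpace, idx_a: np.ndarray,
                        idx_b: np.ndarray) -> np.ndarray:
    """Hamming distance matrix between two genotype index sets."""
    da = space.digits(idx_a)
    db = space.digits(idx_b)
    d = np.zeros((len(idx_a), len(idx_b)), dtype=np.int16)
    for p in range(space.length):
        d += da[:, [p]] != db[None, :, p]
    return d


def _covariance_form_posterior(prior: VCPrior, obs: GaussianObservations,
                               jitter: float = 1e-10,
                               center: bool = True) -> PosteriorGaussian:
    space = obs.space
    lam = np.asarray(prior.lambdas)
    if center and lam[0] != 0.0:
        raise ValueError("lambda_0 must be 0; the mean is fitted by centering")
    K = prior.kernel_operator(space)
    profile = prior.covariance_by_distance(space)
    k0 = profile[0]
    ybar = float(np.mean(obs.y)) if center else 0.0
    yc = obs.y - ybar
    idx = obs.obs_indices
    n_obs = obs.n_obs

    diag = obs.noise_var + jitter * max(k0, 1.0)
    if n_obs <= DIRECT_SOLVE_MAX_OBS:
        D = _pairwise_distances(space, idx, idx)
        A = profile[D]
        A[np.diag_indices(n_obs)] += diag
        factor = cho_factor(A, lower=True)
        solve = lambda b: cho_solve(factor, b)
        diagnostics = {"solver": "cholesky", "n_obs": n_obs}
    else:
        def A_mv(v):
            full = np.zeros(space.n_genotypes)
            full[idx] = v
            return K(full)[idx] + diag * v

        A_op = LinearMap(n_obs, A_mv)

        def solve(b):
            x, info = cg_solve(A_op, b)
            return x

        diagnostics = {"solver": "cg", "n_obs": n_obs}

    alpha_vec = solve(yc)
    full_alpha = np.zeros(space.n_genotypes)
    full_alpha[idx] = alpha_vec
    mean = ybar + K(full_alpha)

    def cov_quad(w, w2=None):
        kw = K(w)
        zw = solve(kw[idx])
        if w2 is None:
            return float(np.dot(w, kw) - np.dot(kw[idx], zw))
        kw2 = K(w2)
        return float(np.dot(w, kw2) - np.dot(kw2[idx], zw))

    def var_batch(targets):
        Ktx = profile[_pairwise_distances(space, targets, idx)]
        if n_obs <= DIRECT_SOLVE_MAX_OBS:
            Z = cho_solve(factor, Ktx.T)
        else:
            Z = np.column_stack([solve(row) for row in Ktx])
        quad = np.einsum("ij,ji->i", Ktx, Z)
        return np.maximum(k0 - quad, 0.0)

    return PosteriorGaussian(space, mean, _cov_quad=cov_quad,
                             _var_batch=var_batch, diagnostics=diagnostics)


def _precision_form_posterior(prior: DeltaPrior,
                              obs: GaussianObservations) -> PosteriorGaussian:
    if np.any(obs.noise_var <= 0):
        raise ValueError(
            "precision-form MAP needs strictly positive noise variances; "
            "use MEI interpolation for exact (noiseless) constraints"
        )
    space = obs.space
    C = prior.precision_operator(space)
    idx = obs.obs_indices
    inv_var = np.zeros(space.n_genotypes)
    inv_var[idx] = 1.0 / obs.noise_var

    def H_mv(v):
        return C(v) + inv_var * v

    H = LinearMap(space.n_genotypes, H_mv)
    rhs = np.zeros(space.n_genotypes)
    rhs[idx] = obs.y / obs.noise_var
    try:
        mean, info = cg_solve(H, rhs)
    except ConvergenceError as err:
        raise ConvergenceError(
            "posterior solve failed; the improper prior leaves a component "
            "of the landscape unidentified by these observations "
            f"(order < {prior.P} structure needs enough coverage): {err}"
        ) from err

    def cov_quad(w, w2=None):
        z, _ = cg_solve(H, w2 if w2 is not None else w)
        return float(np.dot(w, z))

    return PosteriorGaussian(space, mean, _cov_quad=cov_quad,
                             diagnostics={"solver": "cg", **info})


def gaussian_posterior(prior, obs: GaussianObservations,
                       center: bool = True) -> PosteriorGaussian:
    """Exact Gaussian posterior under a Gaussian likelihood.

    Dispatches on the prior form: covariance form for :class:`VCPrior`
    (``f_hat = K_{.x}(K_xx + D)^{-1} y``), precision form for
    :class:`DeltaPrior` (``(C + E D^{-1} E') f_hat = E D^{-1} y`` by CG).
    ``center`` (VC priors only) treats the global mean as an improper flat
    prior by centering the data; disable it for a strict zero-mean prior.
    """
    if isinstance(prior, VCPrior):
        return _covariance_form_posterior(prior, obs, center=center)
    if isinstance(prior, DeltaPrior):
        return _precision_form_posterior(prior, obs)
    raise TypeError(f"unsupported prior type {type(prior).__name__}")


# ---------------------------------------------------------------------------
# Minimum epistasis interpolation
# ---------------------------------------------------------------------------

def mei(obs: GaussianObservations, P: int = 2,
        a: float | None = None) -> PosteriorGaussian:
    """Minimum epistasis interpolation / regression.

    With all noise variances zero (and ``a`` unset) the observations are
    matched exactly and the unobserved phenotypes minimize the total squared
    local P-way epistatic coefficient ``f' Delta(P) f``; the result is
    independent of ``a``.  With noise, this is MAP inference under
    ``DeltaPrior(P, a)``.
    """
    space = obs.space
    noiseless = np.all(obs.noise_var == 0)
    if not noiseless or a is not None:
        if a is None:
            raise ValueError("noisy MEI requires the prior strength a")
        return _precision_form_posterior(DeltaPrior(P=P, a=a), obs)

    Delta = delta_operator(space, P)
    n = space.n_genotypes
    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[obs.obs_indices] = True
    unobs = np.flatnonzero(~obs_mask)
    full = np.zeros(n)
    full[obs.obs_indices] = obs.y
    if unobs.size == 0:
        return PosteriorGaussian(space, full,
                                 diagnostics={"solver": "none", "iterations": 0})

    rhs = -Delta(full)[unobs]

    def Duu_mv(v):
        padded = np.zeros(n)
        padded[unobs] = v
        return Delta(padded)[unobs]

    try:
        fu, info = cg_solve(LinearMap(unobs.size, Duu_mv), rhs)
    except ConvergenceError as err:
        raise ConvergenceError(
            "MEI interpolation is underdetermined for this observation set "
            f"(constraints do not pin down the unobserved block): {err}"
        ) from err
    full[unobs] = fu
    return PosteriorGaussian(space, full, diagnostics={"solver": "cg", **info})


# ---------------------------------------------------------------------------
# Empirical distance correlation and kernel alignment
# ---------------------------------------------------------------------------

def empirical_distance_correlation(obs: GaussianObservations) -> pd.DataFrame:
    """Covariance/correlation of measured values by Hamming distance.

    ``cov(d)`` averages ``(y_i - ybar)(y_j - ybar)`` over all observed pairs
    at distance d; the d = 0 entry is the sample variance minus the mean
    noise variance (so the profile estimates the signal covariance under
    independent measurement errors).  Distances with no pairs get NaN.
    """
    space = obs.space
    ell = space.length
    yc = obs.y - obs.y.mean()
    cov = np.full(ell + 1, np.nan)
    counts = np.zeros(ell + 1, dtype=np.int64)

    if obs.is_complete and space.is_uniform:
        # complete data: f' A_d f via one order-components sweep
        order = np.argsort(obs.obs_indices)
        f = yc[order]
        comps = order_components(space, f)
        norms = np.array([np.dot(c, c) for c in comps])
        W = krawtchouk_matrix(ell, space.alpha)
        alpha = space.alpha
        n = space.n_genotypes
        for d in range(ell + 1):
            n_d = comb(ell, d) * (alpha - 1) ** d
            counts[d] = n * n_d
            # eigenvalue of the distance-d class on the order-k subspace is
            # K_d(k) = W[d, k], so f' A_d f = sum_k W[d, k] ||f_k||^2
            cov[d] = float(W[d] @ norms) / counts[d]
    else:
        chunk = 512
        idx = obs.obs_indices
        dig = space.digits(idx)
        sums = np.zeros(ell + 1)
        for start in range(0, obs.n_obs, chunk):
            sl = slice(start, min(start + chunk, obs.n_obs))
            d = np.zeros((sl.stop - sl.start, obs.n_obs), dtype=np.int16)
            for p in range(ell):
                d += dig[sl, [p]] != dig[None, :, p]
            prod = np.outer(yc[sl], yc)
            for dd in range(ell + 1):
                mask = d == dd
                counts[dd] += int(mask.sum())
                sums[dd] += float(prod[mask].sum())
        with np.errstate(invalid="ignore"):
            cov = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    cov[0] = cov[0] - float(np.mean(obs.noise_var))
    if np.isfinite(cov[0]) and cov[0] > 0:
        corr = cov / cov[0]
    else:  # zero or negative signal variance: correlation undefined
        corr = np.full_like(cov, np.nan)
    return pd.DataFrame({
        "distance": np.arange(ell + 1),
        "covariance": cov,
        "correlation": corr,
        "n_pairs": counts,
    })


def fit_variance_components(obs: GaussianObservations) -> VCPrior:
    """Kernel alignment: fit ``lambda_k >= 0`` to the empirical covariance decay.

    Solves the (ell+1)-dimensional nonnegative weighted least squares problem
    ``min_lambda sum_d w_d (cov_emp(d) - sum_k lambda_k b_k(d))^2`` with pair
    counts as weights; the order-0 column is dropped (the global mean is
    handled by centering).
    """
    space = obs.space
    table = empirical_distance_correlation(obs)
    valid = table["n_pairs"].to_numpy() > 0
    cov = table["covariance"].to_numpy()[valid]
    w = table["n_pairs"].to_numpy()[valid].astype(float)
    if valid.sum() < 2:
        raise ValueError("too few populated distance classes for alignment")
    B = order_distance_basis(space)[valid][:, 1:]
    sw = np.sqrt(w)
    lam_pos, rnorm = nnls(B * sw[:, None], cov * sw)
    if not np.any(lam_pos > 0):
        raise ValueError("kernel alignment found no signal (all lambda_k = 0)")
    return VCPrior((0.0, *lam_pos))


def vc_regression(obs: GaussianObservations,
                  prior: VCPrior | None = None) -> PosteriorGaussian:
    """VC regression: Gaussian posterior under a variance-component prior.

    If no prior is given it is first fitted by kernel alignment.
    """
    if prior is None:
        prior = fit_variance_components(obs)
    return _covariance_form_posterior(prior, obs)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "U",
    "R": "AG", "Y": "CTU", "W": "ATU", "S": "CG", "K": "GTU", "M": "AC",
    "B": "CGTU", "D": "AGTU", "H": "ACTU", "V": "ACG", "N": "ACGTU",
}


def expand_pattern(space: SequenceSpace, pattern: str) -> np.ndarray:
    """Uniform-average weight vector over genotypes matching a degenerate pattern.

    ``N`` (and the other IUPAC degeneracy codes, restricted to each site's
    alphabet) matches any allele; concrete symbols match themselves.  Weights
    sum to one over the matching set.
    """
    if len(pattern) != space.length:
        raise ValueError(f"pattern length {len(pattern)} != {space.length}")
    site_vectors = []
    for p, ch in enumerate(pattern):
        alph = space.site_alphabets[p]
        if ch in alph:
            allowed = [ch]
        elif ch == "N":  # wildcard on any alphabet
            allowed = list(alph)
        else:
            allowed = [c for c in alph if c in _IUPAC.get(ch, "")]
        if not allowed:
            raise ValueError(f"pattern symbol {ch!r} matches nothing at site {p}")
        u = np.array([1.0 if c in allowed else 0.0 for c in alph])
        site_vectors.append(u / u.sum())
    w = site_vectors[0]
    for u in site_vectors[1:]:
        w = np.multiply.outer(w, u)
    return w.reshape(-1)


def mutation_contrast_weights(space: SequenceSpace, background: str, site: int,
                              from_sym: str, to_sym: str) -> np.ndarray:
    """Weights for the effect of ``from -> to`` at one site in a background."""
    bg = list(background)
    bg[site] = from_sym
    i = space.encode(bg)
    bg[site] = to_sym
    j = space.encode(bg)
    w = np.zeros(space.n_genotypes)
    w[j] += 1.0
    w[i] -= 1.0
    return w


def posterior_contrast(posterior: PosteriorGaussian,
                       weights: np.ndarray | None = None,
                       pattern: str | None = None,
                       level: float = 0.95) -> dict:
    """Mean, sd and credible interval of a linear functional of the landscape."""
    if (weights is None) == (pattern is None):
        raise ValueError("pass exactly one of weights or pattern")
    if pattern is not None:
        weights = expand_pattern(posterior.space, pattern)
    w = np.asarray(weights, dtype=float)
    mean = float(np.dot(w, posterior.mean))
    var = posterior.cov_query(w)
    sd = float(np.sqrt(max(var, 0.0)))
    from scipy.stats import norm
    z = float(norm.ppf(0.5 + level / 2))
    return {"mean": mean, "sd": sd,
            "ci_lower": mean - z * sd, "ci_upper": mean + z * sd}


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def sample_prior(space: SequenceSpace, prior, rng) -> Landscape:
    """Draw one landscape from a prior (zero mean).

    VC priors: ``f = sum_k sqrt(lambda_k n / m_k) P_k z`` so the realized
    per-genotype variance of the order-k component has expectation
    ``lambda_k``.  Delta priors: Gaussian on the row space of Delta(P) with
    precision ``(a/s) Delta(P)``; the unpenalized (order < P) component is
    set to zero.
    """
    rng = np.random.default_rng(rng)
    z = rng.standard_normal(space.n_genotypes)
    if isinstance(prior, VCPrior):
        mu = np.sqrt(prior.kernel_eigenvalues(space))
        f = operator_from_order_eigenvalues(space, mu)(z)
        return Landscape(space, f, label="VC prior sample")
    if isinstance(prior, DeltaPrior):
        if not space.is_uniform:
            raise ValueError("Delta prior sampling implemented for uniform spaces")
        if not prior.a > 0:
            raise ValueError("sampling requires a > 0")
        ell, alpha = space.length, space.alpha
        s = prior.coefficient_count(space)
        delta_eig = np.array([alpha ** prior.P * comb(k, prior.P)
                              for k in range(ell + 1)], dtype=float)
        mu = np.zeros(ell + 1)
        nz = delta_eig > 0
        mu[nz] = np.sqrt(s / (prior.a * delta_eig[nz]))
        f = operator_from_order_eigenvalues(space, mu)(z)
        return Landscape(space, f, label="Delta prior sample")
    raise TypeError(f"unsupported prior type {type(prior).__name__}")


def simulate_observations(landscape: Landscape, sigma: float,
                          missing_frac: float, rng) -> GaussianObservations:
    """Observe a random subset of genotypes with i.i.d. Gaussian noise."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(rng)
    n = landscape.space.n_genotypes
    n_obs = max(1, int(round(n * (1 - missing_frac))))
    idx = np.sort(rng.choice(n, size=n_obs, replace=False))
    y = landscape.values[idx] + sigma * rng.standard_normal(n_obs)
    return GaussianObservations(landscape.space, idx, y,
                                np.full(n_obs, sigma ** 2))


def simulate_counts(space: SequenceSpace, pi: np.ndarray, n_total: int,
                    rng) -> CountData:
    """Multinomial draw of ``n_total`` sequences from distribution ``pi``."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (space.n_genotypes,) or np.any(pi < 0):
        raise ValueError("pi must be a nonnegative vector over all genotypes")
    pi = pi / pi.sum()
    rng = np.random.default_rng(rng)
    return CountData(space, rng.multinomial(n_total, pi))
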