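"""Sequence probability distribution estimation (SeqDEFT).

Models a distribution over all sequences as ``pi_i = exp(-phi_i) / Z`` and
places an improper Gaussian prior on the latent field ``phi`` with precision
``(a/s) Delta(P)``, penalizing local order-P epistatic coefficients of
``phi`` while leaving lower-order structure free.  Combined with a
multinomial likelihood over observed counts this gives a convex MAP problem

    minimize  (a/2s) phi' Delta(P) phi + N . phi + N_T log sum_j exp(-phi_j)

solved matrix-free with L-BFGS.  The two limits bracket the model family:
``a = inf`` forces all order-P coefficients to zero (for P = 2, the
independent-sites / PWM model), ``a = 0`` maximizes the bare likelihood
(empirical frequencies).  The hyperparameter ``a`` is chosen by K-fold
cross-validation of the held-out log-likelihood over a geometric grid, and
uncertainty is quantified by a Laplace approximation at the MAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .gp import CountData, PosteriorGaussian
from .linop import (LinearMap, cg_solve, delta_operator,
                    epistatic_coefficient_count, order_components)
from .space import Landscape, SequenceSpace

__all__ = ["SeqDEFTFit", "seqdeft_map", "seqdeft_cv", "laplace_posterior",
           "default_a_grid"]

GRAD_TOL = 1e-9


@dataclass
class SeqDEFTFit:
    """MAP estimate of a sequence probability distribution."""

    space: SequenceSpace
    phi: np.ndarray  # latent field; pi = exp(-phi), already normalized
    pi: np.ndarray
    P: int
    a: float
    diagnostics: dict = field(default_factory=dict)

    def log_likelihood(self, counts: np.ndarray) -> float:
        """Multinomial log-likelihood of counts under the fitted distribution."""
        counts = np.asarray(counts)
        mask = counts > 0
        with np.errstate(divide="ignore"):
            logpi = np.log(self.pi)
        if np.any(mask & ~np.isfinite(logpi)):
            return -np.inf
        return float(np.dot(counts[mask], logpi[mask]))

    def to_landscape(self, label: str = "phi") -> Landscape:
        return Landscape(self.space, self.phi, label=label)


def _normalize_phi(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the additive gauge so that ``sum exp(-phi) = 1``; return (phi, pi)."""
    phi = phi + logsumexp(-phi)
    return phi, np.exp(-phi)


def _nll(phi: np.ndarray, counts: np.ndarray, n_total: int):
    """Multinomial negative log-likelihood (up to constants) and its gradient."""
    val = float(np.dot(counts, phi)) + n_total * float(logsumexp(-phi))
    grad = counts - n_total * softmax(-phi)
    return val, grad


def _product_model_phi(data: CountData, floor: float = 1e-12) -> np.ndarray:
    """phi of the independent-sites (product of marginals) distribution."""
    space = data.space
    freq = data.frequencies.reshape(space.shape)
    phi = np.zeros(space.shape)
    for p in range(space.length):
        axes = tuple(q for q in range(space.length) if q != p)
        marg = np.maximum(freq.sum(axis=axes), floor)
        marg = marg / marg.sum()
        shape = [1] * space.length
        shape[p] = -1
        phi = phi - np.log(marg).reshape(shape)
    return phi.reshape(-1)


def seqdeft_map(data: CountData, P: int = 2, a: float = 1.0,
                phi0: np.ndarray | None = None,
                grad_tol: float = GRAD_TOL) -> SeqDEFTFit:
    """MAP estimate of the sequence distribution at prior strength ``a``.

    ``a = np.inf`` fits the maximum-entropy model with interactions only of
    order < P (the independent-sites model for P = 2); ``a = 0`` returns the
    empirical frequencies (``phi`` is infinite on unobserved sequences).
    Finite ``a`` solves the penalized convex problem with L-BFGS, warm-started
    at ``phi0`` (default: the order-< P fit).
    """
    space = data.space
    counts = data.counts.astype(float)
    n_total = data.n_total

    if a == 0:
        pi = data.frequencies
        with np.errstate(divide="ignore"):
            phi = -np.log(pi)
        return SeqDEFTFit(space, phi, pi, P=P, a=0.0,
                          diagnostics={"mode": "empirical"})

    if np.isinf(a):
        # optimize over the order-< P subspace: phi = Proj_{<P} theta
        def project(v):
            comps = order_components(space, v)
            return comps[:P].sum(axis=0)

        def fun(theta):
            phi = project(theta)
            val, grad = _nll(phi, counts, n_total)
            return val / n_total, project(grad) / n_total

        theta0 = _product_model_phi(data) if P >= 2 else \
            np.full(space.n_genotypes, np.log(space.n_genotypes))
        res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "gtol": grad_tol,
                                "ftol": 1e-16})
        phi, pi = _normalize_phi(project(res.x))
        gnorm = float(np.max(np.abs(res.jac)))
        _check_convergence(gnorm, grad_tol, res)
        return SeqDEFTFit(space, phi, pi, P=P, a=np.inf,
                          diagnostics={"mode": "max_ent", "grad_norm": gnorm,
                                       "iterations": res.nit})

    s = epistatic_coefficient_count(space, P)
    C = (a / s) * delta_operator(space, P)

    def fun(phi):
        Cphi = C(phi)
        nll_val, nll_grad = _nll(phi, counts, n_total)
        val = 0.5 * float(np.dot(phi, Cphi)) + nll_val
        return val / n_total, (Cphi + nll_grad) / n_total

    if phi0 is None:
        phi0 = seqdeft_map(data, P=P, a=np.inf, grad_tol=1e-6).phi
    res = minimize(fun, phi0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "gtol": grad_tol, "ftol": 1e-16})
    gnorm = float(np.max(np.abs(res.jac)))
    _check_convergence(gnorm, grad_tol, res)
    phi, pi = _normalize_phi(res.x)
    return SeqDEFTFit(space, phi, pi, P=P, a=float(a),
                      diagnostics={"mode": "map", "grad_norm": gnorm,
                                   "iterations": res.nit})


def _check_convergence(gnorm: float, grad_tol: float, res) -> None:
    # L-BFGS may stop on ftol; accept if the gradient is nonetheless small
    if gnorm > max(1e3 * grad_tol, 1e-5):
        raise RuntimeError(
            f"SeqDEFT optimization did not converge: grad norm {gnorm:.2e}, "
            f"status {res.status} ({res.message})"
        )


def default_a_grid(space: SequenceSpace, data: CountData, P: int = 2,
                   n_points: int = 20, decades: float = 6.0) -> np.ndarray:
    """Geometric grid of ``a`` values centered on the ``s / N_T`` heuristic."""
    center = epistatic_coefficient_count(space, P) / data.n_total
    half = decades / 2
    return center * np.logspace(-half, half, n_points)


def seqdeft_cv(data: CountData, P: int = 2, grid: np.ndarray | None = None,
               folds: int = 5, rng=0) -> tuple[float, pd.DataFrame]:
    """Choose the prior strength by K-fold cross-validated log-likelihood.

    The ``N_T`` individual observations are randomly assigned to folds; for
    each candidate ``a`` (the grid plus the two limit models) the MAP fit on
    the training folds is scored by the held-out multinomial log-likelihood.
    Returns the maximizer of the mean held-out log-likelihood and the full
    CV table (one row per (a, fold), with ``a = inf`` and ``a = 0`` rows
    included).
    """
    space = data.space
    if grid is None:
        grid = default_a_grid(space, data, P)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid of a values")
    rng = np.random.default_rng(rng)

    # scatter the N_T draws into folds, genotype by genotype
    draws = np.repeat(np.arange(space.n_genotypes), data.counts)
    fold_of = rng.permuted(np.arange(len(draws)) % folds)
    fold_counts = np.zeros((folds, space.n_genotypes), dtype=np.int64)
    for f in range(folds):
        np.add.at(fold_counts[f], draws[fold_of == f], 1)
    if np.any(fold_counts.sum(axis=1) == 0):
        raise ValueError("a fold received zero observations; reduce folds")

    a_values = [np.inf, *sorted(grid, reverse=True), 0.0]
    rows = []
    for f in range(folds):
        train = CountData(space, data.counts - fold_counts[f])
        test = fold_counts[f]
        phi_warm = None
        for a in a_values:
            fit = seqdeft_map(train, P=P, a=a, phi0=phi_warm)
            if np.isfinite(a) and a > 0:
                phi_warm = fit.phi
            rows.append({"a": a, "fold": f,
                         "test_log_likelihood": fit.log_likelihood(test)})
    table = pd.DataFrame(rows)
    mean_ll = table.groupby("a")["test_log_likelihood"].mean()
    a_star = float(mean_ll.idxmax())
    return a_star, table


def laplace_posterior(data: CountData, P: int, a: float,
                      fit: SeqDEFTFit) -> PosteriorGaussian:
    """Laplace-approximate Gaussian posterior over ``phi`` at the MAP.

    The Hessian of the negative log posterior is
    ``H = (a/s) Delta(P) + N_T (diag(pi) - pi pi')``; covariance queries are
    CG solves against it.  ``phi`` is only identified up to an additive
    constant, so queried contrasts must be shift-invariant (weights summing
    to zero).
    """
    space = data.space
    if not np.isfinite(a) or a <= 0:
        raise ValueError("Laplace posterior needs finite a > 0")
    s = epistatic_coefficient_count(space, P)
    C = (a / s) * delta_operator(space, P)
    pi = fit.pi
    n_total = data.n_total

    def H_mv(v):
        return C(v) + n_total * (pi * v - pi * np.dot(pi, v))

    H = LinearMap(space.n_genotypes, H_mv)

    def cov_quad(w, w2=None):
        rhs = w2 if w2 is not None else w
        for vec in (w, rhs):
            if abs(vec.sum()) > 1e-8 * np.linalg.norm(vec) * np.sqrt(len(vec)):
                raise ValueError(
                    "phi is identified only up to an additive constant; "
                    "covariance queries must use weights summing to zero"
                )
        z, _ = cg_solve(H, rhs)
        z = z - z.mean()  # stay orthogonal to the null space
        return float(np.dot(w, z))

    return PosteriorGaussian(space, fit.phi, _cov_quad=cov_quad,
                             diagnostics={"solver": "cg", "hessian": "laplace"})
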