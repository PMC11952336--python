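"""Matrix-free structured operators on sequence space.

The matrices needed for landscape inference and decomposition (graph
Laplacian ``L``, the epistasis operators ``Delta(P)``, the orthogonal
projections ``P_U`` and ``P_k``, and distance-dependent covariance kernels)
are all dense or sparse ``n x n`` objects with ``n = prod_p alpha_p``
genotypes, far too large to build explicitly beyond toy spaces.  Every one of
them, however, factors over sites: they are sums of Kronecker products of
small per-site matrices.  This module represents them as
:class:`LinearMap` objects that only ever touch length-``n`` vectors.

Key algebraic facts used throughout:

* The Hamming-graph Laplacian is the Kronecker sum of per-site complete-graph
  Laplacians, ``L = sum_p I (x) ... (x) (alpha_p I - J) (x) ... (x) I``.
* ``P_U = (x)_p F_p`` with ``F_p = I - J/alpha_p`` for sites in ``U`` and
  ``F_p = J/alpha_p`` otherwise; summing over ``|U| = k`` gives the order-k
  projection ``P_k``.  The generating identity
  ``(x)_p (J/alpha_p + z (I - J/alpha_p)) = sum_k z^k P_k`` yields all order
  components of a vector in one ``O(ell^2 n)`` sweep (:func:`order_components`).
* ``Delta(P) = sum_{|V|=P} (x)_p (alpha_p I - J if p in V else I)``; the
  quadratic form ``f' Delta(P) f`` enumerates every local P-way epistatic
  coefficient squared.
* On uniform-alphabet spaces any matrix whose entries depend only on Hamming
  distance is simultaneously diagonalized by the ``P_k``; its eigenvalues are
  Krawtchouk transforms of the distance profile, and equivalently it is an
  ell-degree polynomial in ``L``.

Dense materializations (``to_dense``) are provided for spaces up to 4096
genotypes and exist purely as test oracles.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Callable, Sequence

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .space import SequenceSpace

__all__ = [
    "LinearMap",
    "kron_apply",
    "laplacian",
    "delta_operator",
    "epistatic_coefficient_count",
    "projection_apply",
    "projection_operator",
    "order_components",
    "krawtchouk_matrix",
    "distance_kernel",
    "distance_profile_eigenvalues",
    "polynomial_in_laplacian",
    "laplacian_polynomial_coefficients",
    "cg_solve",
    "ConvergenceError",
]

DENSE_ORACLE_MAX = 4096


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class LinearMap:
    """A linear operator defined by its action on vectors.

    Thin wrapper pairing a dimension with a matvec callable; supports
    composition into scipy iterative solvers and dense materialization for
    small test spaces.
    """

    def __init__(self, dim: int, matvec: Callable[[np.ndarray], np.ndarray],
                 symmetric: bool = True):
        self.dim = int(dim)
        self._matvec = matvec
        self.symmetric = symmetric

    def __call__(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.dim,):
            raise ValueError(f"expected vector of length {self.dim}, got {v.shape}")
        return self._matvec(v)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self(v)

    def quad(self, v: np.ndarray) -> float:
        """Quadratic form ``v' A v``."""
        return float(np.dot(v, self(v)))

    def __add__(self, other: "LinearMap") -> "LinearMap":
        if self.dim != other.dim:
            raise ValueError("dimension mismatch")
        return LinearMap(self.dim, lambda v: self(v) + other(v),
                         symmetric=self.symmetric and other.symmetric)

    def __rmul__(self, scalar: float) -> "LinearMap":
        s = float(scalar)
        return LinearMap(self.dim, lambda v: s * self(v), symmetric=self.symmetric)

    def as_scipy(self) -> LinearOperator:
        return LinearOperator((self.dim, self.dim), matvec=self._matvec,
                              rmatvec=self._matvec if self.symmetric else None,
                              dtype=float)

    def to_dense(self) -> np.ndarray:
        """Materialize as a dense array.  Test oracle only; capped at 4096."""
        if self.dim > DENSE_ORACLE_MAX:
            raise ValueError(
                f"refusing to materialize a {self.dim}x{self.dim} operator "
                f"(oracle cap {DENSE_ORACLE_MAX})"
            )
        out = np.empty((self.dim, self.dim))
        e = np.zeros(self.dim)
        for j in range(self.dim):
            e[j] = 1.0
            out[:, j] = self(e)
            e[j] = 0.0
        return out


# ---------------------------------------------------------------------------
# Kronecker products
# ---------------------------------------------------------------------------

def kron_apply(site_matrices: Sequence[np.ndarray], v: np.ndarray) -> np.ndarray:
    """Apply ``(x)_p M_p`` to ``v`` without forming the Kronecker product.

    ``site_matrices[p]`` must be ``alpha_p x alpha_p``; ``v`` has length
    ``prod_p alpha_p``.  Uses the mixed Kronecker matrix-vector identity:
    reshape ``v`` into an ``ell``-way tensor and contract one site at a time.
    """
    mats = [np.asarray(M, dtype=float) for M in site_matrices]
    shape = []
    for p, M in enumerate(mats):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"site {p}: matrix must be square, got {M.shape}")
        shape.append(M.shape[0])
    v = np.asarray(v, dtype=float)
    n = int(np.prod(shape))
    if v.shape != (n,):
        raise ValueError(f"vector length {v.shape} incompatible with sites {shape}")
    t = v.reshape(shape)
    for p, M in enumerate(mats):
        t = np.moveaxis(np.tensordot(M, t, axes=([1], [p])), 0, p)
    return t.reshape(-1)


def _site_avg(t: np.ndarray, axis: int) -> np.ndarray:
    """Apply ``J/alpha`` along one tensor axis (average, broadcast back)."""
    return np.broadcast_to(t.mean(axis=axis, keepdims=True), t.shape)


# ---------------------------------------------------------------------------
# Laplacian
# ---------------------------------------------------------------------------

def laplacian(space: SequenceSpace) -> LinearMap:
    """Graph Laplacian ``L = D - A`` of the Hamming graph as a LinearMap.

    Kronecker-sum form: per site, ``alpha_p I - J``; eigenvalues on uniform
    spaces are ``alpha * k`` on the order-k subspace.
    """
    shape = space.shape
    sizes = space.alphabet_sizes

    def matvec(v: np.ndarray) -> np.ndarray:
        t = v.reshape(shape)
        out = np.zeros_like(t)
        for p in range(space.length):
            out += sizes[p] * t - sizes[p] * _site_avg(t, p)
        return out.reshape(-1)

    return LinearMap(space.n_genotypes, matvec)


def laplacian_apply(space: SequenceSpace, v: np.ndarray) -> np.ndarray:
    return laplacian(space)(np.asarray(v, dtype=float))


# ---------------------------------------------------------------------------
# Local epistasis operator Delta(P)
# ---------------------------------------------------------------------------

def delta_operator(space: SequenceSpace, P: int = 2) -> LinearMap:
    """The order-P local epistasis operator ``Delta(P)``.

    ``f' Delta(P) f`` equals the sum over all P-subsets of sites, all
    unordered allele pairs at each chosen site, and all backgrounds at the
    remaining sites, of the squared P-way local epistatic coefficient (the
    P-th finite difference of ``f`` over the corresponding subcube).  Each
    P-subset contributes a Kronecker product with the complete-graph
    Laplacian ``alpha_p I - J`` at chosen sites and identity elsewhere, since
    ``g' (alpha I - J) g = sum_{a<b} (g_a - g_b)^2``.

    Symmetric positive semi-definite; annihilates any landscape whose
    interactions all have order ``< P``.
    """
    ell = space.length
    if not 1 <= P <= ell:
        raise ValueError(f"P must be in [1, {ell}], got {P}")
    shape = space.shape
    sizes = space.alphabet_sizes
    subsets = list(combinations(range(ell), P))

    def matvec(v: np.ndarray) -> np.ndarray:
        t = v.reshape(shape)
        out = np.zeros_like(t)
        for V in subsets:
            term = t
            for p in V:
                term = sizes[p] * term - sizes[p] * _site_avg(term, p)
            out += term
        return out.reshape(-1)

    return LinearMap(space.n_genotypes, matvec)


def epistatic_coefficient_count(space: SequenceSpace, P: int = 2) -> int:
    """Number ``s`` of local P-way epistatic coefficients enumerated by Delta(P).

    One coefficient per (P-subset of sites, unordered allele pair at each
    chosen site, background at the remaining sites):
    ``s = sum_{|V|=P} prod_{p in V} C(alpha_p, 2) * prod_{p not in V} alpha_p``.
    """
    ell = space.length
    if not 1 <= P <= ell:
        raise ValueError(f"P must be in [1, {ell}], got {P}")
    sizes = space.alphabet_sizes
    total = 0
    for V in combinations(range(ell), P):
        term = 1
        for p in range(ell):
            term *= comb(int(sizes[p]), 2) if p in V else int(sizes[p])
        total += term
    return total


# ---------------------------------------------------------------------------
# Orthogonal projections P_U, P_k
# ---------------------------------------------------------------------------

def order_components(space: SequenceSpace, v: np.ndarray) -> np.ndarray:
    """All order components ``f_k = P_k v`` for ``k = 0..ell`` in one sweep.

    Uses the site-wise generating identity
    ``(x)_p (A_p + z B_p) = sum_k z^k P_k`` with ``A_p = J/alpha_p`` and
    ``B_p = I - J/alpha_p``: a dynamic program over sites maintains the
    vector coefficients of the polynomial in ``z``.  Numerically stable
    (only averages and differences) and valid for mixed alphabets.

    Returns an array of shape ``(ell + 1, n)`` whose rows sum to ``v``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (space.n_genotypes,):
        raise ValueError("vector length mismatch")
    shape = space.shape
    coeffs = [v.reshape(shape)]
    for p in range(space.length):
        avgs = [_site_avg(t, p) for t in coeffs]
        new = []
        for j in range(len(coeffs) + 1):
            t = np.zeros(shape)
            if j < len(coeffs):
                t = t + avgs[j]
            if j >= 1:
                t = t + coeffs[j - 1] - avgs[j - 1]
            new.append(t)
        coeffs = new
    return np.stack([t.reshape(-1) for t in coeffs])


def projection_apply(space: SequenceSpace, selector, v: np.ndarray) -> np.ndarray:
    """Apply ``P_k`` (selector = order int) or ``P_U`` (selector = site set).

    ``P_U`` is the Kronecker product with ``I - J/alpha_p`` on sites in ``U``
    and the averaging matrix ``J/alpha_p`` elsewhere, matching the entrywise
    formula ``P_U(x, x') = alpha^{-ell} prod_{p in U} (alpha - 1 or -1) ...``
    on uniform spaces and its per-site generalization otherwise.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (space.n_genotypes,):
        raise ValueError("vector length mismatch")
    if np.isscalar(selector) or isinstance(selector, (int, np.integer)):
        k = int(selector)
        if not 0 <= k <= space.length:
            raise ValueError(f"order must be in [0, {space.length}], got {k}")
        return order_components(space, v)[k]
    U = frozenset(int(p) for p in selector)
    if U and (min(U) < 0 or max(U) >= space.length):
        raise ValueError(f"site subset {sorted(U)} out of range")
    t = v.reshape(space.shape)
    for p in range(space.length):
        a = _site_avg(t, p)
        t = (t - a) if p in U else a
    return t.reshape(-1)


def projection_operator(space: SequenceSpace, selector) -> LinearMap:
    sel = selector if np.isscalar(selector) else frozenset(selector)
    return LinearMap(space.n_genotypes, lambda v: projection_apply(space, sel, v))


# ---------------------------------------------------------------------------
# Distance kernels (uniform-alphabet spaces)
# ---------------------------------------------------------------------------

def krawtchouk_matrix(ell: int, alpha: int) -> np.ndarray:
    """Krawtchouk values ``W[k, d] = K_k(d)`` for the Hamming scheme H(ell, alpha).

    ``K_k(d) = sum_j (-1)^j (alpha-1)^{k-j} C(d, j) C(ell-d, k-j)``.  Column
    ``d`` holds the entries (times ``alpha^ell``) of ``P_k`` between genotype
    pairs at distance ``d``; row ``k`` gives the eigenvalue of the distance-d
    adjacency class on the order-k subspace (the scheme is self-dual).
    """
    W = np.zeros((ell + 1, ell + 1))
    for k in range(ell + 1):
        for d in range(ell + 1):
            W[k, d] = sum(
                (-1) ** j * (alpha - 1) ** (k - j) * comb(d, j) * comb(ell - d, k - j)
                for j in range(min(k, d) + 1)
            )
    return W


def distance_profile_eigenvalues(space: SequenceSpace,
                                 values_by_distance: np.ndarray) -> np.ndarray:
    """Order-subspace eigenvalues of the matrix with entries ``w(d(i, j))``."""
    if not space.is_uniform:
        raise ValueError("distance kernels require a uniform alphabet size")
    w = np.asarray(values_by_distance, dtype=float)
    ell = space.length
    if w.shape != (ell + 1,):
        raise ValueError(f"need {ell + 1} values (one per distance), got {w.shape}")
    W = krawtchouk_matrix(ell, space.alpha)
    # mu_k = sum_d w(d) K_d(k): transpose of the Krawtchouk matrix
    return W.T @ w


def operator_from_order_eigenvalues(space: SequenceSpace,
                                    eigenvalues: np.ndarray) -> LinearMap:
    """Operator ``sum_k mu_k P_k`` applied through :func:`order_components`."""
    mu = np.asarray(eigenvalues, dtype=float)
    if mu.shape != (space.length + 1,):
        raise ValueError("need one eigenvalue per interaction order")

    def matvec(v: np.ndarray) -> np.ndarray:
        comps = order_components(space, v)
        return np.tensordot(mu, comps, axes=1)

    return LinearMap(space.n_genotypes, matvec)


def distance_kernel(space: SequenceSpace,
                    values_by_distance: np.ndarray) -> LinearMap:
    """Symmetric operator whose (i, j) entry is ``values_by_distance[d(i, j)]``.

    Such matrices are polynomials in the graph Laplacian; here they are
    applied in their spectral form ``sum_k mu_k P_k`` with ``mu`` the
    Krawtchouk transform of the distance profile, which is algebraically
    identical and numerically stable.  Uniform alphabets only.
    """
    mu = distance_profile_eigenvalues(space, values_by_distance)
    return operator_from_order_eigenvalues(space, mu)


def laplacian_polynomial_coefficients(space: SequenceSpace,
                                      order_eigenvalues: np.ndarray) -> np.ndarray:
    """Coefficients ``c_i`` with ``sum_i c_i L^i = sum_k mu_k P_k``.

    Solves the (ell+1)-point interpolation problem through the Laplacian
    eigenvalues ``alpha * k`` in the Newton basis (divided differences), which
    is far better conditioned than the raw Vandermonde system.  Intended for
    ell <= 16 in double precision.
    """
    if not space.is_uniform:
        raise ValueError("polynomial-in-L route requires uniform alphabets")
    mu = np.asarray(order_eigenvalues, dtype=float)
    ell = space.length
    x = space.alpha * np.arange(ell + 1, dtype=float)
    # divided differences -> Newton form -> monomial basis (Horner expansion)
    dd = mu.astype(float).copy()
    for j in range(1, ell + 1):
        dd[j:] = (dd[j:] - dd[j - 1:-1]) / (x[j:] - x[:-j])
    from numpy.polynomial import polynomial as npoly

    poly = np.array([dd[ell]])
    for j in range(ell - 1, -1, -1):
        poly = npoly.polymul(poly, np.array([-x[j], 1.0]))
        poly[0] += dd[j]
    out = np.zeros(ell + 1)
    out[: len(poly)] = poly
    return out


def polynomial_in_laplacian(space: SequenceSpace,
                            coefficients: np.ndarray) -> LinearMap:
    """The operator ``sum_i c_i L^i`` evaluated by repeated Laplacian products."""
    c = np.asarray(coefficients, dtype=float)
    L = laplacian(space)

    def matvec(v: np.ndarray) -> np.ndarray:
        out = c[0] * v
        power = v
        for ci in c[1:]:
            power = L(power)
            out = out + ci * power
        return out

    return LinearMap(space.n_genotypes, matvec)


# ---------------------------------------------------------------------------
# Conjugate gradients
# ---------------------------------------------------------------------------

def cg_solve(op, b: np.ndarray, tol: float = 1e-8, maxiter: int | None = None,
             x0: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
    """Solve ``A x = b`` for a symmetric PSD LinearMap via conjugate gradients.

    Raises :class:`ConvergenceError` if the relative residual does not reach
    ``tol`` within ``maxiter`` iterations (default ``10 * sqrt(dim)``, floored
    at 200).
    """
    A = op.as_scipy() if isinstance(op, LinearMap) else op
    n = A.shape[0]
    if maxiter is None:
        maxiter = max(200, int(10 * np.sqrt(n)))
    iters = 0

    def count(_):
        nonlocal iters
        iters += 1

    x, info = cg(A, b, rtol=tol, atol=0.0, maxiter=maxiter, x0=x0, callback=count)
    bnorm = np.linalg.norm(b)
    resid = np.linalg.norm(A @ x - b) / (bnorm if bnorm > 0 else 1.0)
    if info != 0:
        raise ConvergenceError(
            f"CG did not converge in {maxiter} iterations "
            f"(relative residual {resid:.3e}, tol {tol:.1e})"
        )
    return x, {"iterations": iters, "residual": resid}
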