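"""Weak-mutation evolutionary dynamics and diffusion-axis embedding.

Under weak mutation a population occupies a single genotype and evolves by
sequential fixation: a continuous-time Markov chain on the Hamming graph
whose rate from genotype ``i`` to a neighbor ``j`` is the mutation rate
times the relative fixation probability ``S / (1 - exp(-S))`` with scaled
selection coefficient ``S = c (f(j) - f(i))``.  With a time-reversible
mutation model the chain is reversible with stationary distribution
``pi(i) proportional to pi_M(i) exp(c f(i))``.

The visualization embeds genotypes using the subdominant right eigenvectors
of the rate matrix ``Q``, rescaled as ``u_k = r_k / sqrt(-lambda_k)`` (with
``r_k' D_pi r_k = 1``) so that squared embedding distances, summed over all
axes, equal commute times between genotypes.  The eigenvalue magnitudes give
relaxation times ``-1 / lambda_k``: the timescales on which each landscape
feature constrains evolution (neutral baseline: the reciprocal of the
smallest allele count across sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.sparse.linalg import LinearOperator, eigsh
from scipy.special import logsumexp

from .space import Landscape, SequenceSpace

__all__ = ["EvolutionModel", "Embedding", "build_rate_matrix",
           "stationary_distribution", "calibrate_c", "embed", "export_layout",
           "fixation_factor"]

DENSE_EIG_MAX = 2048


def fixation_factor(S: np.ndarray) -> np.ndarray:
    """Relative fixation probability ``S / (1 - exp(-S))``.

    Tends to 1 as S -> 0, exceeds 1 for beneficial changes, and decays like
    ``|S| exp(S)`` for deleterious ones (low but non-zero).  Evaluated in a
    branch-stable form on both tails.
    """
    S = np.asarray(S, dtype=float)
    out = np.ones_like(S)
    pos = S > 0
    neg = S < 0
    with np.errstate(over="ignore", invalid="ignore"):
        out[pos] = S[pos] / (-np.expm1(-S[pos]))
        out[neg] = S[neg] * np.exp(S[neg]) / np.expm1(S[neg])
    return out


def _site_generator_stationary(M: np.ndarray) -> np.ndarray:
    """Stationary distribution of a per-site mutation rate matrix."""
    alpha = M.shape[0]
    G = M.astype(float).copy()
    np.fill_diagonal(G, 0.0)
    np.fill_diagonal(G, -G.sum(axis=1))
    w, V = np.linalg.eig(G.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(V[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class EvolutionModel:
    """Reversible weak-mutation rate matrix on a complete landscape."""

    landscape: Landscape
    c: float
    site_rates: list[np.ndarray]  # per-site mutation rate matrices
    site_stationary: list[np.ndarray] = field(default_factory=list)

    @property
    def space(self) -> SequenceSpace:
        return self.landscape.space

    def neutral_log_stationary(self) -> np.ndarray:
        """log pi_M, the stationary distribution of mutation alone."""
        space = self.space
        out = np.zeros(space.shape)
        for p, pi_p in enumerate(self.site_stationary):
            shape = [1] * space.length
            shape[p] = -1
            out = out + np.log(pi_p).reshape(shape)
        return out.reshape(-1)

    def _pair_iter(self):
        """Yield (site, a, b, rate_array) for every ordered allele pair a != b."""
        space = self.space
        F = self.landscape.values.reshape(space.shape)
        for p, M in enumerate(self.site_rates):
            Ft = np.moveaxis(F, p, 0)
            for a in range(M.shape[0]):
                for b in range(M.shape[0]):
                    if a == b or M[a, b] == 0:
                        continue
                    S = self.c * (Ft[b] - Ft[a])
                    yield p, a, b, M[a, b] * fixation_factor(S)

    def rate_apply(self, v: np.ndarray) -> np.ndarray:
        """Q v, using ``(Qv)_i = sum_{j ~ i} Q(i, j) (v_j - v_i)``."""
        space = self.space
        t = np.asarray(v, dtype=float).reshape(space.shape)
        out = np.zeros(space.shape)
        for p, a, b, rate in self._pair_iter():
            vt = np.moveaxis(t, p, 0)
            ot = np.moveaxis(out, p, 0)
            ot[a] += rate * (vt[b] - vt[a])
        return out.reshape(-1)

    def rate_transpose_apply(self, u: np.ndarray) -> np.ndarray:
        """Q' u (probability-flow direction)."""
        space = self.space
        t = np.asarray(u, dtype=float).reshape(space.shape)
        out = np.zeros(space.shape)
        for p, a, b, rate in self._pair_iter():
            ut = np.moveaxis(t, p, 0)
            ot = np.moveaxis(out, p, 0)
            ot[b] += rate * ut[a]
            ot[a] -= rate * ut[a]
        return out.reshape(-1)

    def rate_dense(self) -> np.ndarray:
        """Dense Q for small models (test oracle / dense eigensolve)."""
        n = self.space.n_genotypes
        if n > DENSE_EIG_MAX:
            raise ValueError(f"dense Q capped at {DENSE_EIG_MAX} states")
        out = np.empty((n, n))
        e = np.zeros(n)
        for j in range(n):
            e[j] = 1.0
            out[:, j] = self.rate_apply(e)
            e[j] = 0.0
        return out


def build_rate_matrix(landscape: Landscape, c: float,
                      site_rates: list[np.ndarray] | None = None
                      ) -> EvolutionModel:
    """Assemble the weak-mutation rate matrix for a landscape.

    ``site_rates[p]`` holds per-site mutation rates (off-diagonal entries;
    diagonals are ignored); default is rate 1 between all alleles, measuring
    time in units of the inverse mutation rate.  Each site model must be
    time-reversible; this is checked against its stationary distribution.
    """
    space = landscape.space
    if site_rates is None:
        site_rates = [np.ones((a, a)) for a in space.alphabet_sizes]
    if len(site_rates) != space.length:
        raise ValueError("need one mutation matrix per site")
    stationaries = []
    for p, M in enumerate(site_rates):
        M = np.asarray(M, dtype=float)
        if M.shape != (space.alphabet_sizes[p],) * 2:
            raise ValueError(f"site {p}: mutation matrix has wrong shape")
        off = M[~np.eye(M.shape[0], dtype=bool)]
        if np.any(off < 0):
            raise ValueError(f"site {p}: negative mutation rates")
        pi_p = _site_generator_stationary(M)
        flux = pi_p[:, None] * M
        np.fill_diagonal(flux, 0.0)
        if not np.allclose(flux, flux.T, rtol=1e-8, atol=1e-12):
            raise ValueError(f"site {p}: mutation model is not time-reversible")
        stationaries.append(pi_p)
        site_rates[p] = M
    return EvolutionModel(landscape, float(c), site_rates, stationaries)


def stationary_distribution(model: EvolutionModel) -> np.ndarray:
    """Stationary distribution ``pi(i) prop pi_M(i) exp(c f(i))``."""
    logpi = model.neutral_log_stationary() + model.c * model.landscape.values
    return np.exp(logpi - logsumexp(logpi))


def calibrate_c(landscape: Landscape, target_mean: float | None = None,
                mode: str = "mean") -> float:
    """Choose the selection scale ``c``.

    ``mode="mean"`` root-finds the ``c`` whose stationary distribution has the
    requested mean phenotype (monotone in c, solved by bisection);
    ``mode="probability"`` returns 1 for landscapes already on a
    log-probability scale, where the stationary distribution then equals the
    modeled probabilities exactly.
    """
    if mode == "probability":
        return 1.0
    if target_mean is None:
        raise ValueError("mean mode requires target_mean")
    f = landscape.values
    lo, hi = float(f.min()), float(f.max())
    if not lo < target_mean < hi:
        raise ValueError(
            f"target mean {target_mean} outside the phenotype range ({lo}, {hi})"
        )

    def gap(c):
        logpi = c * f
        pi = np.exp(logpi - logsumexp(logpi))
        return float(np.dot(pi, f)) - target_mean

    span = 1.0
    for _ in range(60):
        if gap(-span) < 0 < gap(span):
            return float(brentq(gap, -span, span, xtol=1e-12))
        span *= 2.0
    raise RuntimeError("failed to bracket c")


@dataclass
class Embedding:
    """Diffusion-axis coordinates of a genotype-phenotype map."""

    space: SequenceSpace
    coords: np.ndarray          # (n, m): u_2 .. u_{m+1}
    eigenvalues: np.ndarray     # lambda_1 = 0 >= lambda_2 >= ... (length m+1)
    relaxation_times: np.ndarray  # -1 / lambda_k for k >= 2 (length m)
    stationary: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def relaxation_table(self, top: int = 20) -> pd.DataFrame:
        m = min(top, len(self.relaxation_times))
        return pd.DataFrame({
            "diffusion_axis": np.arange(1, m + 1),
            "eigenvalue": self.eigenvalues[1:m + 1],
            "relaxation_time": self.relaxation_times[:m],
        })


def embed(model: EvolutionModel, n_axes: int = 10) -> Embedding:
    """Diffusion-axis embedding from the top of the spectrum of ``Q``.

    Solves the symmetrized eigenproblem ``D^{1/2} Q D^{-1/2}`` (dense for
    small models, Lanczos otherwise), back-transforms to right eigenvectors
    ``r_k`` with ``r_k' D_pi r_k = 1``, and rescales to
    ``u_k = r_k / sqrt(-lambda_k)``.  Axis signs are fixed by requiring
    nonnegative pi-weighted skewness.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    space = model.space
    n = space.n_genotypes
    if n_axes > n - 1:
        raise ValueError(f"at most {n - 1} axes exist for {n} genotypes")
    pi = stationary_distribution(model)
    sq = np.sqrt(pi)

    k = n_axes + 1
    if n <= DENSE_EIG_MAX:
        Q = model.rate_dense()
        A = (sq[:, None] * Q) / sq[None, :]
        A = 0.5 * (A + A.T)
        w, V = np.linalg.eigh(A)
        order = np.argsort(w)[::-1]
        w, V = w[order[:k]], V[:, order[:k]]
    else:
        def mv(v):
            return sq * model.rate_apply(v / sq)

        A_op = LinearOperator((n, n), matvec=mv, dtype=float)
        w, V = eigsh(A_op, k=k, which="LA")
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]

    # lambda_1 is 0 up to numerical error; clip it exactly
    eigenvalues = w.copy()
    eigenvalues[0] = 0.0
    rates = -eigenvalues[1:]
    if np.any(rates <= 0):
        raise RuntimeError("eigensolver returned a nonnegative subdominant "
                           "eigenvalue; model may be disconnected")
    R = V / sq[:, None]          # right eigenvectors, r' D_pi r = 1
    U = R[:, 1:] / np.sqrt(rates)[None, :]
    for j in range(U.shape[1]):  # deterministic orientation
        skew = float(np.dot(pi, U[:, j] ** 3))
        if skew < 0 or (skew == 0 and U[np.argmax(np.abs(U[:, j]) > 0), j] < 0):
            U[:, j] = -U[:, j]
    return Embedding(space, U, eigenvalues, 1.0 / rates, pi)


def _edge_table(space: SequenceSpace) -> np.ndarray:
    """All Hamming-graph edges as an (n_edges, 2) index array (i < j)."""
    n = space.n_genotypes
    dig = space.digits(np.arange(n))
    radix = space.radix
    chunks = []
    for p in range(space.length):
        alpha = space.alphabet_sizes[p]
        for a in range(alpha):
            for b in range(a + 1, alpha):
                i = np.flatnonzero(dig[:, p] == a)
                chunks.append(np.column_stack([i, i + (b - a) * radix[p]]))
    edges = np.vstack(chunks)
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


def export_layout(embedding: Embedding, landscape: Landscape,
                  axes: tuple[int, ...] = (1, 2),
                  paths: list[list[int]] | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Node/edge (and optional path) tables for plotting the embedding.

    ``axes`` are 1-based diffusion-axis numbers.  Paths are ordered genotype
    index lists; every consecutive pair must be Hamming neighbors.
    """
    space = embedding.space
    for ax in axes:
        if not 1 <= ax <= embedding.n_axes:
            raise ValueError(f"diffusion axis {ax} out of range "
                             f"(1..{embedding.n_axes})")
    nodes = pd.DataFrame({"sequence": space.genotype_strings()})
    for ax in axes:
        nodes[f"axis_{ax}"] = embedding.coords[:, ax - 1]
    nodes["phenotype"] = landscape.values
    nodes["stationary"] = embedding.stationary

    edges = pd.DataFrame(_edge_table(space), columns=["i", "j"])

    path_df = None
    if paths is not None:
        rows = []
        for pid, path in enumerate(paths):
            for step, (i, j) in enumerate(zip(path[:-1], path[1:])):
                if space.hamming_distances([i], [j])[0] != 1:
                    raise ValueError(
                        f"path {pid}, step {step}: genotypes {i} and {j} "
                        f"are not Hamming neighbors"
                    )
            for step, i in enumerate(path):
                rows.append({"path": pid, "step": step, "index": int(i)})
        path_df = pd.DataFrame(rows)
    return nodes, edges, path_df
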