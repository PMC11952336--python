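"""Independent brute-force oracles used across the test suite.

Everything here works by exhaustive enumeration or dense linear algebra and
never calls the structured-operator code paths it is used to check.
"""

from itertools import combinations, product

import numpy as np


def brute_force_mean_squared_epistasis(space, f, P):
    """Enumerate every local P-way epistatic coefficient and average squares.

    A coefficient is the P-th order finite difference of ``f`` over the
    2^P subcube defined by a P-subset of sites, one unordered allele pair per
    chosen site, and a fixed background at the remaining sites.
    Returns (mean squared coefficient, number of coefficients).
    """
    ell = space.length
    sizes = space.alphabet_sizes
    fa = np.asarray(f, dtype=float).reshape(space.shape)
    total = 0.0
    count = 0
    for V in combinations(range(ell), P):
        pair_lists = [list(combinations(range(sizes[p]), 2)) for p in V]
        bg_sites = [p for p in range(ell) if p not in V]
        bg_ranges = [range(sizes[p]) for p in bg_sites]
        for pairs in product(*pair_lists):
            for bg in product(*bg_ranges):
                eps = 0.0
                for bits in product((0, 1), repeat=P):
                    geno = [0] * ell
                    for p, b in zip(bg_sites, bg):
                        geno[p] = b
                    for (site, pair), bit in zip(zip(V, pairs), bits):
                        geno[site] = pair[bit]
                    eps += (-1) ** sum(bits) * fa[tuple(geno)]
                total += eps ** 2
                count += 1
    return total / count, count


def dense_subset_projector(space, U):
    """P_U built from explicit per-site Kronecker factors."""
    mats = []
    for p in range(space.length):
        a = space.alphabet_sizes[p]
        J = np.ones((a, a)) / a
        mats.append(np.eye(a) - J if p in U else J)
    out = mats[0]
    for M in mats[1:]:
        out = np.kron(out, M)
    return out


def dense_hamming_adjacency(space):
    n = space.n_genotypes
    A = np.zeros((n, n))
    for i in range(n):
        A[i, space.neighbors(i)] = 1.0
    return A


def dense_gp_posterior(K, idx, y, noise_var):
    """Closed-form zero-mean GP conditioning (no centering)."""
    Kxx = K[np.ix_(idx, idx)] + np.diag(noise_var)
    sol = np.linalg.solve(Kxx, y)
    mean = K[:, idx] @ sol
    cov = K - K[:, idx] @ np.linalg.solve(Kxx, K[idx, :])
    return mean, cov


def hitting_times(Q):
    """Expected hitting times H[i, j] of a continuous-time chain, densely."""
    n = Q.shape[0]
    H = np.zeros((n, n))
    for j in range(n):
        keep = [i for i in range(n) if i != j]
        H[keep, j] = np.linalg.solve(Q[np.ix_(keep, keep)], -np.ones(n - 1))
    return H
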