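"""Epistasis summaries of complete landscapes.

Two complementary views of the genetic architecture of a landscape ``f``:

* the mean squared local P-way epistatic coefficient, a quadratic form
  ``(1/s) f' Delta(P) f`` measuring how much mutational effects change
  between neighboring backgrounds; and
* the orthogonal decomposition ``f = sum_k f_k = sum_U f_U`` into interaction
  orders ``k`` and site subsets ``U``, whose squared norms partition the
  landscape's variance (Parseval).

"Variance" throughout is the population variance over the uniform
distribution on genotypes, which makes the partition exact; the order-0
component carries the squared mean and is excluded from variance totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .linop import (delta_operator, epistatic_coefficient_count,
                    order_components, projection_apply)
from .space import Landscape

__all__ = [
    "VarianceDecomposition",
    "mean_squared_epistatic_coefficient",
    "variance_components",
    "subset_variances",
]

SUBSET_ENUMERATION_MAX_SITES = 16


@dataclass
class VarianceDecomposition:
    """Variance of a landscape partitioned by interaction order and site subset.

    Attributes
    ----------
    by_order:
        ``by_order[k]`` is the variance carried by order-k interactions
        (``k = 0`` holds the squared mean, not counted toward variance).
    by_subset:
        Optional map from site subsets ``U`` to the variance of ``f_U``.
    site_order_profile:
        ``[p, k]`` = variance of interactions of order k involving site p.
    pair_profile:
        Square matrix: lower triangle holds pairwise (``|U| = 2``) variance
        for each pair, upper triangle the higher-order (``|U| > 2``) variance
        involving the pair.
    """

    by_order: np.ndarray
    by_subset: dict[frozenset, float] | None = None
    site_order_profile: np.ndarray | None = None
    pair_profile: np.ndarray | None = None
    total_variance: float = field(default=0.0)

    @property
    def percent_by_order(self) -> np.ndarray:
        """Percent of total variance per epistatic order (k >= 1)."""
        tot = self.by_order[1:].sum()
        out = np.zeros_like(self.by_order)
        if tot > 0:
            out[1:] = 100.0 * self.by_order[1:] / tot
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "order": np.arange(len(self.by_order)),
            "variance": self.by_order,
            "percent": self.percent_by_order,
        })


def mean_squared_epistatic_coefficient(landscape: Landscape, P: int = 2
                                       ) -> tuple[float, float]:
    """Mean squared local P-way epistatic coefficient and its square root.

    ``eps2 = (1/s) f' Delta(P) f`` where ``s`` counts the enumerated
    coefficients (site subsets x allele pairs x backgrounds).  ``P = 1``
    gives the mean squared mutational effect.
    """
    space = landscape.space
    s = epistatic_coefficient_count(space, P)
    quad = delta_operator(space, P).quad(landscape.values)
    eps2 = quad / s
    return eps2, float(np.sqrt(max(eps2, 0.0)))


def variance_components(landscape: Landscape) -> VarianceDecomposition:
    """Variance explained by interactions of each order ``k = 0..ell``.

    ``by_order[k] = mean((P_k f)^2)``; orders >= 1 sum to ``Var(f)``.
    """
    comps = order_components(landscape.space, landscape.values)
    by_order = np.mean(comps ** 2, axis=1)
    return VarianceDecomposition(by_order=by_order,
                                 total_variance=landscape.variance)


def subset_variances(landscape: Landscape,
                     subsets: list | None = None,
                     aggregate: bool = True) -> VarianceDecomposition:
    """Variance explained by interactions among specific site subsets.

    With ``subsets`` given, only those are computed.  Otherwise all ``2^ell``
    subsets are enumerated (``ell <= 16``) and, if ``aggregate``, summarized
    into the per-site-by-order profile and the pairwise/higher-order pair
    matrix.
    """
    space = landscape.space
    ell = space.length
    f = landscape.values
    n = space.n_genotypes

    if subsets is None:
        if ell > SUBSET_ENUMERATION_MAX_SITES:
            raise ValueError(
                f"exhaustive subset enumeration needs <= "
                f"{SUBSET_ENUMERATION_MAX_SITES} sites (got {ell}); pass an "
                f"explicit list of target subsets instead"
            )
        subsets = [frozenset(U) for k in range(ell + 1)
                   for U in combinations(range(ell), k)]
    else:
        subsets = [frozenset(int(p) for p in U) for U in subsets]

    by_subset: dict[frozenset, float] = {}
    for U in subsets:
        fU = projection_apply(space, U, f)
        by_subset[U] = float(np.dot(fU, fU) / n)

    by_order = np.zeros(ell + 1)
    for U, var in by_subset.items():
        by_order[len(U)] += var

    dec = VarianceDecomposition(by_order=by_order, by_subset=by_subset,
                                total_variance=landscape.variance)
    if aggregate:
        site_order = np.zeros((ell, ell + 1))
        pair = np.zeros((ell, ell))
        for U, var in by_subset.items():
            k = len(U)
            for p in U:
                site_order[p, k] += var
            for p, q in combinations(sorted(U), 2):
                if k == 2:
                    pair[q, p] += var  # lower triangle: pairwise
                else:
                    pair[p, q] += var  # upper triangle: higher order
        dec.site_order_profile = site_order
        dec.pair_profile = pair
    return dec
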