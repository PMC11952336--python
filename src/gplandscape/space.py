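"""Combinatorial sequence spaces and the Hamming graph.

A sequence space is the set of all sequences of fixed length ``ell`` where
site ``p`` draws its symbol from an ordered alphabet of size ``alpha_p``
(alphabets may differ between sites).  Genotypes are indexed lexicographically
with a mixed-radix encoding, the first site being the most significant digit,
so a complete landscape is simply a vector of length ``prod_p alpha_p``.

The Hamming graph connects genotypes that differ at exactly one site; all the
structured matrices used elsewhere in the package (graph Laplacian, epistasis
operators, projections, distance kernels) live on this graph and are exposed
as matrix-free linear maps in :mod:`gplandscape.linop`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SequenceSpace", "Landscape"]


@dataclass(frozen=True)
class SequenceSpace:
    """All sequences of fixed length over (possibly site-specific) alphabets.

    Parameters
    ----------
    site_alphabets:
        One ordered collection of distinct symbols per site.  Strings are
        convenient: ``SequenceSpace(["ACGT"] * 9)`` is the space of all DNA
        9-mers with ``4**9 = 262,144`` genotypes.

    Notes
    -----
    Genotype indices are mixed-radix: ``index = sum_p digit_p * radix_p`` with
    ``radix_p = prod_{q > p} alpha_q``, so site 0 is the most significant
    digit and genotypes enumerate in lexicographic order of their symbols
    (in the user-supplied alphabet order).
    """

    site_alphabets: tuple[tuple[str, ...], ...]
    _symbol_index: tuple[dict, ...] = field(repr=False, compare=False, default=())

    def __init__(self, site_alphabets: Iterable[Sequence[str]]):
        alphabets = tuple(tuple(a) for a in site_alphabets)
        if len(alphabets) < 1:
            raise ValueError("need at least one site")
        for p, alph in enumerate(alphabets):
            if len(alph) < 2:
                raise ValueError(f"site {p}: alphabet must have >= 2 symbols")
            if len(set(alph)) != len(alph):
                raise ValueError(f"site {p}: duplicate symbols in {alph!r}")
        object.__setattr__(self, "site_alphabets", alphabets)
        object.__setattr__(
            self,
            "_symbol_index",
            tuple({c: i for i, c in enumerate(a)} for a in alphabets),
        )

    # -- basic geometry ----------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.site_alphabets)

    @property
    def alphabet_sizes(self) -> np.ndarray:
        return np.array([len(a) for a in self.site_alphabets], dtype=int)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(int(a) for a in self.alphabet_sizes)

    @property
    def n_genotypes(self) -> int:
        return int(np.prod(self.alphabet_sizes, dtype=object))

    @property
    def is_uniform(self) -> bool:
        """True when every site has the same number of alleles."""
        sizes = self.alphabet_sizes
        return bool(np.all(sizes == sizes[0]))

    @property
    def alpha(self) -> int:
        if not self.is_uniform:
            raise ValueError("space has site-specific alphabet sizes")
        return int(self.alphabet_sizes[0])

    @property
    def radix(self) -> np.ndarray:
        """Place value of each site in the mixed-radix encoding."""
        sizes = self.alphabet_sizes
        r = np.ones(self.length, dtype=np.int64)
        r[:-1] = np.cumprod(sizes[::-1])[::-1][1:]
        return r

    @property
    def n_edges(self) -> int:
        """Number of Hamming-graph edges, ``n * sum_p (alpha_p - 1) / 2``."""
        return self.n_genotypes * int((self.alphabet_sizes - 1).sum()) // 2

    # -- encoding ----------------------------------------------------------
    def encode(self, sequence: Sequence[str]) -> int:
        if len(sequence) != self.length:
            raise ValueError(
                f"sequence length {len(sequence)} != space length {self.length}"
            )
        idx = 0
        for p, (c, lookup) in enumerate(zip(sequence, self._symbol_index)):
            try:
                d = lookup[c]
            except KeyError:
                raise ValueError(
                    f"symbol {c!r} at site {p} not in alphabet "
                    f"{''.join(self.site_alphabets[p])!r}"
                ) from None
            idx = idx * len(self.site_alphabets[p]) + d
        return idx

    def decode(self, index: int) -> str:
        if not 0 <= index < self.n_genotypes:
            raise IndexError(f"index {index} out of range [0, {self.n_genotypes})")
        out = []
        for alph in reversed(self.site_alphabets):
            index, d = divmod(index, len(alph))
            out.append(alph[d])
        return "".join(reversed(out))

    def encode_many(self, sequences: Iterable[Sequence[str]]) -> np.ndarray:
        return np.array([self.encode(s) for s in sequences], dtype=np.int64)

    def digits(self, indices) -> np.ndarray:
        """Mixed-radix digits (allele index at each site), shape ``(n, ell)``."""
        idx = np.asarray(indices, dtype=np.int64)
        scalar = idx.ndim == 0
        idx = np.atleast_1d(idx)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_genotypes):
            raise IndexError("genotype index out of range")
        out = np.empty((idx.size, self.length), dtype=np.int64)
        rem = idx.copy()
        for p in range(self.length - 1, -1, -1):
            rem, out[:, p] = np.divmod(rem, self.alphabet_sizes[p])
        return out[0] if scalar else out

    def genotype_strings(self, indices=None) -> np.ndarray:
        """Sequences for the given indices (default: all, in encoding order)."""
        if indices is None:
            indices = np.arange(self.n_genotypes)
        dig = np.atleast_2d(self.digits(indices))
        cols = [
            np.array(self.site_alphabets[p], dtype="U1")[dig[:, p]]
            for p in range(self.length)
        ]
        joined = cols[0].astype(f"U{self.length}")
        for c in cols[1:]:
            joined = np.char.add(joined, c)
        return joined

    # -- Hamming graph -----------------------------------------------------
    def neighbors(self, index: int) -> np.ndarray:
        """Indices of all genotypes at Hamming distance 1."""
        dig = self.digits(index)
        radix = self.radix
        out = []
        for p in range(self.length):
            base = index - dig[p] * radix[p]
            for a in range(self.alphabet_sizes[p]):
                if a != dig[p]:
                    out.append(base + a * radix[p])
        return np.array(out, dtype=np.int64)

    def hamming_distances(self, indices_a, indices_b) -> np.ndarray:
        """Element-wise Hamming distance between two index arrays."""
        da = self.digits(indices_a)
        db = self.digits(indices_b)
        return np.count_nonzero(np.atleast_2d(da) != np.atleast_2d(db), axis=1)


@dataclass
class Landscape:
    """A complete genotype-phenotype map: one value per genotype.

    ``values[i]`` is the phenotype of ``space.decode(i)``; the vector may hold
    a measured trait ``f``, a latent field ``phi``, or a log-probability.
    """

    space: SequenceSpace
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.space.n_genotypes,):
            raise ValueError(
                f"landscape has {self.values.shape} values; "
                f"space has {self.space.n_genotypes} genotypes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("landscape values must all be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def variance(self) -> float:
        """Population variance over the uniform distribution on genotypes."""
        return float(np.var(self.values))
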