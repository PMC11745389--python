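"""Genotype-space combinatorics and complete fitness landscapes.

Genotypes over ``L`` biallelic sites are encoded two ways:

* as an integer index whose binary expansion gives the site states, with
  site 0 in the least significant bit (used for O(1) table lookup), and
* as a bit sequence (tuple/array of 0/1, site 0 first) at API boundaries.

The all-zero genotype is the germline reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "FitnessLandscape",
    "EpistasisCoefficients",
    "Sublandscape",
    "bits_to_index",
    "index_to_bits",
    "hamming",
    "mutational_neighbors",
    "find_local_optima",
    "project_sublandscape",
]

Genotype = tuple[int, ...]


def bits_to_index(bits: Sequence[int]) -> int:
    """Encode a bit sequence (site 0 first) as an integer index."""
    idx = 0
    for i, b in enumerate(bits):
        if b not in (0, 1):
            raise ValueError(f"genotype entries must be 0/1, got {b!r} at site {i}")
        idx |= int(b) << i
    return idx


def index_to_bits(idx: int, L: int) -> Genotype:
    """Decode an integer index into a bit tuple of length ``L``."""
    return tuple((idx >> i) & 1 for i in range(L))


def hamming(a: int, b: int) -> int:
    """Hamming distance between two integer-encoded genotypes."""
    return int(bin(a ^ b).count("1"))


def mutational_neighbors(g: Sequence[int], L: int) -> set[Genotype]:
    """All genotypes one mutation away from ``g``.

    Returns exactly ``L`` genotypes, each differing from ``g`` at a single
    site.
    """
    g = tuple(int(b) for b in g)
    if len(g) != L:
        raise ValueError(f"genotype has length {len(g)}, expected L={L}")
    if any(b not in (0, 1) for b in g):
        raise ValueError("genotype entries must be 0/1")
    out = set()
    for i in range(L):
        flipped = list(g)
        flipped[i] = 1 - flipped[i]
        out.add(tuple(flipped))
    return out


@dataclass
class FitnessLandscape:
    """A complete map from all ``2**L`` genotypes to real fitness.

    Parameters
    ----------
    L:
        Number of biallelic sites.
    fitness:
        Array of ``2**L`` fitness values indexed by the integer genotype
        encoding (site 0 = least significant bit).
    site_labels:
        Ordered site identifiers (defaults to ``["0", ..., str(L-1)]``).
    """

    L: int
    fitness: np.ndarray
    site_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        if self.fitness.shape != (2**self.L,):
            raise ValueError(
                f"fitness table has {self.fitness.size} entries, expected {2**self.L}"
            )
        if self.site_labels is None:
            self.site_labels = [str(i) for i in range(self.L)]
        if len(self.site_labels) != self.L:
            raise ValueError("site_labels length must equal L")

    # -- lookups ---------------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return 2**self.L

    @property
    def germline(self) -> Genotype:
        return (0,) * self.L

    @property
    def germline_index(self) -> int:
        return 0

    def value(self, g: int | Sequence[int]) -> float:
        """Fitness of a genotype given as index or bit sequence."""
        return float(self.fitness[self._as_index(g)])

    def _as_index(self, g: int | Sequence[int]) -> int:
        if isinstance(g, (int, np.integer)):
            idx = int(g)
            if not 0 <= idx < self.n_genotypes:
                raise ValueError(f"genotype index {idx} out of range")
            return idx
        return bits_to_index(g)

    def site_index(self, label: str) -> int:
        """Map a site label to its 0-based position."""
        try:
            return self.site_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown site label {label!r}") from None

    # -- topography ------------------------------------------------------

    def neighbor_indices(self, idx: int) -> np.ndarray:
        return idx ^ (1 << np.arange(self.L))

    def local_optima(self) -> np.ndarray:
        """Indices of all strict local fitness maxima (see
        :func:`find_local_optima`)."""
        F = self.fitness
        idx = np.arange(self.n_genotypes)
        strict = np.ones(self.n_genotypes, dtype=bool)
        weak = np.ones(self.n_genotypes, dtype=bool)
        for i in range(self.L):
            Fn = F[idx ^ (1 << i)]
            strict &= F > Fn
            weak &= F >= Fn
        if np.any(weak & ~strict):
            warnings.warn(
                "fitness ties with Hamming-1 neighbors: tied genotypes are "
                "excluded from the local-optima set",
                stacklevel=2,
            )
        return idx[strict]

    def global_optimum(self) -> int:
        """Index of the fittest genotype."""
        return int(np.argmax(self.fitness))

    def referenced_to_germline(self) -> "FitnessLandscape":
        """Copy with fitness shifted so the germline has zero fitness."""
        return FitnessLandscape(
            self.L, self.fitness - self.fitness[0], list(self.site_labels)
        )


@dataclass
class EpistasisCoefficients:
    """Additive, pairwise and triplet terms of the specific epistasis model.

    ``h`` maps site index -> additive field; ``J`` maps strictly increasing
    pairs -> coupling; ``K`` maps strictly increasing triples -> coupling.
    Absent entries are zero.  The model evaluates as::

        F(s) = sum_i h_i s_i + sum_{i<j} J_ij s_i s_j + sum_{i<j<k} K_ijk s_i s_j s_k

    so the all-wild-type genotype always has zero fitness.
    """

    L: int
    h: dict[int, float] = field(default_factory=dict)
    J: dict[tuple[int, int], float] = field(default_factory=dict)
    K: dict[tuple[int, int, int], float] = field(default_factory=dict)
    site_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.site_labels is None:
            self.site_labels = [str(i) for i in range(self.L)]
        for i in self.h:
            self._check_site(i)
        for pair in self.J:
            if len(pair) != 2 or not pair[0] < pair[1]:
                raise ValueError(f"J index {pair} must be a strictly increasing pair")
            for i in pair:
                self._check_site(i)
        for triple in self.K:
            if len(triple) != 3 or not triple[0] < triple[1] < triple[2]:
                raise ValueError(
                    f"K index {triple} must be a strictly increasing triple"
                )
            for i in triple:
                self._check_site(i)

    def _check_site(self, i: int) -> None:
        if not 0 <= i < self.L:
            raise ValueError(f"site index {i} outside [0, {self.L})")

    @property
    def max_order(self) -> int:
        if any(v != 0 for v in self.K.values()):
            return 3
        if any(v != 0 for v in self.J.values()):
            return 2
        return 1 if any(v != 0 for v in self.h.values()) else 0

    def evaluate(self, g: Sequence[int]) -> float:
        """Fitness of one genotype under the specific model."""
        bits = tuple(int(b) for b in g)
        if len(bits) != self.L:
            raise ValueError(f"genotype length {len(bits)} != L={self.L}")
        F = 0.0
        for i, v in self.h.items():
            F += v * bits[i]
        for (i, j), v in self.J.items():
            F += v * bits[i] * bits[j]
        for (i, j, k), v in self.K.items():
            F += v * bits[i] * bits[j] * bits[k]
        return F

    def to_landscape(self) -> FitnessLandscape:
        """Evaluate the model on all ``2**L`` genotypes."""
        n = 2**self.L
        F = np.zeros(n)
        idx = np.arange(n)
        for i, v in self.h.items():
            F += v * ((idx >> i) & 1)
        for (i, j), v in self.J.items():
            F += v * (((idx >> i) & 1) & ((idx >> j) & 1))
        for (i, j, k), v in self.K.items():
            F += v * (((idx >> i) & 1) & ((idx >> j) & 1) & ((idx >> k) & 1))
        return FitnessLandscape(self.L, F, list(self.site_labels))

    def as_vector(self) -> np.ndarray:
        """Flat (h, J, K) vector in deterministic index order."""
        from itertools import combinations

        parts = [self.h.get(i, 0.0) for i in range(self.L)]
        parts += [self.J.get(p, 0.0) for p in combinations(range(self.L), 2)]
        parts += [self.K.get(t, 0.0) for t in combinations(range(self.L), 3)]
        return np.array(parts)


def evaluate_specific(c: EpistasisCoefficients, g: Sequence[int]) -> float:
    """Functional alias for :meth:`EpistasisCoefficients.evaluate`."""
    return c.evaluate(g)


def find_local_optima(ls: FitnessLandscape) -> set[Genotype]:
    """Genotypes strictly fitter than every Hamming-1 neighbor.

    Exact ties with a neighbor disqualify both genotypes (a warning is
    emitted).  The global maximum is always a member when untied.
    """
    return {index_to_bits(int(i), ls.L) for i in ls.local_optima()}


@dataclass
class Sublandscape:
    """A landscape restricted to genotypes with ``n`` sites pinned.

    ``landscape`` is the induced :class:`FitnessLandscape` over the free
    sites; ``lift`` maps induced indices back to parent indices.
    """

    parent: FitnessLandscape
    pinned: dict[int, int]
    free_sites: list[int]
    landscape: FitnessLandscape

    @property
    def n_pinned(self) -> int:
        return len(self.pinned)

    def lift(self, sub_idx: int) -> int:
        """Parent genotype index of an induced genotype index."""
        parent_idx = 0
        for site, state in self.pinned.items():
            parent_idx |= state << site
        for pos, site in enumerate(self.free_sites):
            parent_idx |= ((sub_idx >> pos) & 1) << site
        return parent_idx

    def germline_slice_index(self) -> int:
        """Induced index of the parent germline restricted to free sites
        (all free sites wild-type)."""
        return 0


def project_sublandscape(
    ls: FitnessLandscape, pinned: Mapping[int | str, int]
) -> Sublandscape:
    """Pin a subset of sites and return the induced sublandscape.

    ``pinned`` maps site (index or label) to its fixed state.  The induced
    fitness of each genotype over the free sites equals the parent fitness
    of the composed genotype.
    """
    resolved: dict[int, int] = {}
    for site, state in pinned.items():
        if isinstance(site, str):
            site = ls.site_index(site)
        if not 0 <= site < ls.L:
            raise ValueError(f"pinned site {site} outside [0, {ls.L})")
        if state not in (0, 1):
            raise ValueError(f"pinned state must be 0/1, got {state!r}")
        if site in resolved:
            raise ValueError(f"site {site} pinned twice")
        resolved[site] = int(state)
    if len(resolved) == ls.L:
        raise ValueError("pinning all L sites leaves a degenerate 1-genotype subspace")

    free = [i for i in range(ls.L) if i not in resolved]
    sub_L = len(free)
    sub_idx = np.arange(2**sub_L)
    parent_idx = np.zeros(2**sub_L, dtype=np.int64)
    for site, state in resolved.items():
        parent_idx |= state << site
    for pos, site in enumerate(free):
        parent_idx |= ((sub_idx >> pos) & 1) << site
    induced = FitnessLandscape(
        sub_L, ls.fitness[parent_idx], [ls.site_labels[i] for i in free]
    )
    return Sublandscape(parent=ls, pinned=resolved, free_sites=free, landscape=induced)
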