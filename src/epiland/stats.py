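"""Ruggedness and heterogeneity statistics.

Directed gamma correlations of fitness effects, the generalized gamma(n, d)
over pinned subspaces, the slope-to-roughness funneling ratio, local
distributions of fitness effects, and triplet-coupling summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .landscape import (
    EpistasisCoefficients,
    FitnessLandscape,
    project_sublandscape,
)

__all__ = [
    "gamma_directed",
    "gamma_generalized",
    "GammaRecord",
    "slope_roughness",
    "SlopeRoughness",
    "dfe",
    "k_pair_summary",
    "gamma_row_means",
]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 1 for identical vectors (the additive limit),
    NaN when either side is otherwise degenerate (zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        return 1.0 if x.size == 1 and x[0] == y[0] else float("nan")
    if np.array_equal(x, y):
        return 1.0
    xc = x - x.mean()
    yc = y - y.mean()
    vx = np.dot(xc, xc)
    vy = np.dot(yc, yc)
    scale = max(float(np.max(np.abs(x))), float(np.max(np.abs(y))), 1e-300)
    floor = (1e-9 * scale) ** 2 * x.size
    if vx <= floor and vy <= floor:
        # both effect vectors constant: identical constants mean additivity
        return 1.0 if abs(x.mean() - y.mean()) <= 1e-9 * scale else float("nan")
    if vx <= floor or vy <= floor:
        return float("nan")
    return float(np.dot(xc, yc) / np.sqrt(vx * vy))


def gamma_directed(ls: FitnessLandscape, bidirectional: bool = False) -> np.ndarray:
    """Matrix of directed correlations of fitness effects.

    Entry (i, j) is the Pearson correlation between the effect of mutating
    site j on background s, ``F(s[j]) - F(s)``, and the same effect in the
    presence of mutation i, ``F(s[ij]) - F(s[i])``, over all backgrounds s
    with ``s_i = s_j = 0``.  The diagonal is NaN, as are entries whose
    effect vectors are degenerate (zero variance).

    With ``bidirectional=True`` backgrounds with every (s_i, s_j)
    combination contribute, pairing each j-flip with the same flip after
    toggling site i (sensitivity variant; default off).
    """
    if ls.L < 2:
        raise ValueError("gamma requires L >= 2")
    F = ls.fitness
    idx = np.arange(ls.n_genotypes)
    G = np.full((ls.L, ls.L), np.nan)
    for i in range(ls.L):
        bi = 1 << i
        for j in range(ls.L):
            if i == j:
                continue
            bj = 1 << j
            if bidirectional:
                s = idx[(idx & bj) == 0]
            else:
                s = idx[((idx & bi) == 0) & ((idx & bj) == 0)]
            d_wo = F[s | bj] - F[s]
            d_w = F[(s ^ bi) | bj] - F[s ^ bi]
            G[i, j] = _pearson(d_wo, d_w)
    return G


def _pooled_gamma_at_distance(F: np.ndarray, L: int, d: int) -> float:
    """Correlation of fitness effects between genotypes d mutations apart,
    pooled over all focal sites j and background pairs within a complete
    L-site table."""
    if not 1 <= d <= L - 1:
        raise ValueError(f"distance d={d} infeasible for an {L}-site space")
    idx = np.arange(F.size)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for j in range(L):
        bj = 1 << j
        s = idx[(idx & bj) == 0]
        d_s = F[s | bj] - F[s]
        others = [k for k in range(L) if k != j]
        for sites in combinations(others, d):
            m = 0
            for k in sites:
                m |= 1 << k
            xs.append(d_s)
            ys.append(F[(s ^ m) | bj] - F[s ^ m])
    return _pearson(np.concatenate(xs), np.concatenate(ys))


@dataclass
class GammaRecord:
    """One gamma(n, d) value for a specific pinned-site configuration."""

    n: int
    d: int
    pinned_sites: tuple[int, ...]
    pinned_states: tuple[int, ...]
    gamma: float


def gamma_generalized(
    ls: FitnessLandscape, n: int, d: int
) -> list[GammaRecord]:
    """gamma(n, d) over every choice of n pinned sites and their states.

    For each pinned configuration the correlation of fitness effects is
    pooled over all free focal sites j and all background pairs at Hamming
    distance d inside the (L - n)-dimensional subspace.  Returns the full
    collection (one record per configuration), suitable for violin
    summaries.
    """
    if not 0 <= n <= ls.L - 2:
        raise ValueError(f"n={n} must lie in [0, L-2]")
    if not 1 <= d <= ls.L - n - 1:
        raise ValueError(f"d={d} infeasible with n={n} pinned sites (L={ls.L})")
    records = []
    if n == 0:
        g = _pooled_gamma_at_distance(ls.fitness, ls.L, d)
        return [GammaRecord(0, d, (), (), g)]
    for sites in combinations(range(ls.L), n):
        for states_bits in range(2**n):
            states = tuple((states_bits >> t) & 1 for t in range(n))
            sub = project_sublandscape(ls, dict(zip(sites, states)))
            g = _pooled_gamma_at_distance(sub.landscape.fitness, ls.L - n, d)
            records.append(GammaRecord(n, d, sites, states, g))
    return records


@dataclass
class SlopeRoughness:
    slope: float
    roughness: float
    ratio: float
    h_additive: np.ndarray


def slope_roughness(ls: FitnessLandscape) -> SlopeRoughness:
    """Slope-to-roughness ratio of the best additive approximation.

    The landscape is first re-referenced so the wild-type genotype has
    zero fitness; the additive model ``F_a(s) = sum_i h_i s_i`` is fitted
    by least squares.  slope = mean |h_i|; roughness = RMS residual; a
    perfectly additive landscape reports ratio = +inf.
    """
    F = ls.fitness - ls.fitness[0]
    idx = np.arange(ls.n_genotypes)
    bits = ((idx[:, None] >> np.arange(ls.L)[None, :]) & 1).astype(float)
    h, *_ = np.linalg.lstsq(bits, F, rcond=None)
    resid = F - bits @ h
    s = float(np.mean(np.abs(h)))
    r = float(np.sqrt(np.mean(resid**2)))
    # lstsq residuals on an exactly additive table are pure rounding noise
    if r <= 1e-9 * max(1.0, float(np.sqrt(np.mean(F**2)))):
        r = 0.0
    ratio = float("inf") if r == 0.0 else s / r
    return SlopeRoughness(s, r, ratio, h)


def dfe(ls: FitnessLandscape, g: int | Sequence[int]) -> np.ndarray:
    """Distribution of fitness effects of all L single-site flips from g."""
    idx = ls._as_index(g)
    return ls.fitness[idx ^ (1 << np.arange(ls.L))] - ls.fitness[idx]


def k_pair_summary(c: EpistasisCoefficients) -> np.ndarray:
    """Per-pair triplet-coupling magnitude ``(L-2)^-1 sum_k |K_ijk|``.

    Symmetric L x L matrix with NaN diagonal.
    """
    L = c.L
    if L < 3:
        raise ValueError("triplet summary requires L >= 3")
    M = np.zeros((L, L))
    for (i, j, k), v in c.K.items():
        for a, b in ((i, j), (i, k), (j, k)):
            M[a, b] += abs(v)
            M[b, a] += abs(v)
    M /= L - 2
    np.fill_diagonal(M, np.nan)
    return M


def gamma_row_means(G: np.ndarray) -> np.ndarray:
    """Mean outgoing gamma per site (NaN entries excluded)."""
    return np.nanmean(G, axis=1)
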