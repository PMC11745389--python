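"""NK random landscapes with homogeneous, tunable ruggedness.

Each of L sites interacts with K other sites drawn uniformly without
replacement; per-site fitness contributions are i.i.d. uniform on [0, 1)
over the 2**(K+1) local states, and total fitness is the site mean,
shifted so the all-wild-type genotype has zero fitness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import FitnessLandscape

__all__ = ["NKSpec", "generate_nk", "nk_landscape", "ConstrainedEnsemble", "constrained_nk_ensemble"]


@dataclass
class NKSpec:
    """Full specification of one NK landscape draw (exactly reproducible)."""

    L: int
    K: int
    neighborhoods: np.ndarray  # (L, K) site indices, self excluded
    tables: np.ndarray  # (L, 2**(K+1)) contribution values
    seed: int | None = None

    def __post_init__(self) -> None:
        self.neighborhoods = np.asarray(self.neighborhoods, dtype=int).reshape(
            self.L, self.K
        )
        self.tables = np.asarray(self.tables, dtype=float).reshape(
            self.L, 2 ** (self.K + 1)
        )
        for i in range(self.L):
            nb = self.neighborhoods[i]
            if len(set(nb.tolist())) != self.K or i in nb:
                raise ValueError(f"invalid neighborhood for site {i}: {nb}")


def nk_landscape(spec: NKSpec) -> FitnessLandscape:
    """Evaluate an NK specification on all 2**L genotypes."""
    L, K = spec.L, spec.K
    idx = np.arange(2**L)
    F = np.zeros(2**L)
    for i in range(L):
        sites = np.concatenate([[i], spec.neighborhoods[i]])
        local = np.zeros(2**L, dtype=np.int64)
        for t, s in enumerate(sites):
            local |= ((idx >> s) & 1) << t
        F += spec.tables[i, local]
    F /= L
    F -= F[0]
    return FitnessLandscape(L, F)


def generate_nk(
    L: int, K: int, seed: int | None = None, adjacent: bool = False
) -> tuple[FitnessLandscape, NKSpec]:
    """Draw a random NK landscape; deterministic given the seed.

    ``adjacent=True`` uses cyclically adjacent neighborhoods instead of the
    default random ones.
    """
    if not 0 <= K <= L - 1:
        raise ValueError(f"K={K} must lie in [0, L-1]")
    rng = np.random.default_rng(seed)
    if adjacent:
        nbh = np.array(
            [[(i + t + 1) % L for t in range(K)] for i in range(L)], dtype=int
        ).reshape(L, K)
    else:
        nbh = np.empty((L, K), dtype=int)
        others = np.arange(L)
        for i in range(L):
            pool = others[others != i]
            nbh[i] = rng.choice(pool, size=K, replace=False)
    tables = rng.random((L, 2 ** (K + 1)))
    spec = NKSpec(L, K, nbh, tables, seed)
    return nk_landscape(spec), spec


@dataclass
class ConstrainedEnsemble:
    """NK draws accepted to match a target topography exactly."""

    landscapes: list[FitnessLandscape]
    specs: list[NKSpec]
    target_optima_count: int
    target_distance: int
    attempts_used: int
    complete: bool = True

    def __len__(self) -> int:
        return len(self.landscapes)

    @property
    def acceptance_rate(self) -> float:
        return len(self.landscapes) / max(1, self.attempts_used)


def constrained_nk_ensemble(
    L: int,
    K: int,
    n_optima: int,
    distance: int,
    size: int,
    seed: int | None = None,
    max_attempts: int = 100_000,
) -> ConstrainedEnsemble:
    """Rejection-sample NK landscapes with a fixed number of local optima
    and a fixed germline-to-global-optimum Hamming distance.

    Draws are kept only when both constraints hold exactly, preserving the
    NK distribution conditioned on topography.  If ``max_attempts`` runs
    out a partial ensemble is returned with ``complete=False``.
    """
    rng = np.random.default_rng(seed)
    kept_ls: list[FitnessLandscape] = []
    kept_spec: list[NKSpec] = []
    attempts = 0
    while len(kept_ls) < size and attempts < max_attempts:
        attempts += 1
        sub_seed = int(rng.integers(2**63))
        ls, spec = generate_nk(L, K, seed=sub_seed)
        optima = ls.local_optima()
        if optima.size != n_optima:
            continue
        fmax = ls.global_optimum()
        if bin(fmax).count("1") != distance:
            continue
        kept_ls.append(ls)
        kept_spec.append(spec)
    return ConstrainedEnsemble(
        kept_ls,
        kept_spec,
        n_optima,
        distance,
        attempts,
        complete=len(kept_ls) == size,
    )
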