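"""Evolutionary dynamics on complete landscapes.

Two regimes:

* strong-selection weak-mutation (SSWM) adaptive walks, represented as an
  absorbing Markov chain whose absorbing states are the local fitness
  optima, with transition probabilities proportional to positive fitness
  increments; and
* Wright-Fisher dynamics of a finite population on a ring lattice, where
  node i is replaced each generation by a neighbor within distance r drawn
  with probability proportional to exp(fitness), followed by a per-locus
  mutation sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landscape import FitnessLandscape

__all__ = [
    "TransitionMatrix",
    "build_transition_matrix",
    "absorbing_probabilities",
    "sample_sswm_walk",
    "WFConfig",
    "PopulationTrajectory",
    "wf_step",
    "wf_simulate",
    "success_rate",
    "SuccessRecord",
    "max_occupancy_profile",
]


# ---------------------------------------------------------------------------
# SSWM absorbing chain


@dataclass
class TransitionMatrix:
    """SSWM Markov chain over all 2**L genotypes.

    ``P`` is the full (dense) row-stochastic matrix; ``absorbing`` the
    sorted indices of absorbing states (local optima and, with a warning,
    tie plateaus); ``transient`` the rest.  ``Q`` and ``R`` are the
    transient-transient and transient-absorbing blocks.
    """

    P: np.ndarray
    absorbing: np.ndarray
    transient: np.ndarray

    @property
    def Q(self) -> np.ndarray:
        return self.P[np.ix_(self.transient, self.transient)]

    @property
    def R(self) -> np.ndarray:
        return self.P[np.ix_(self.transient, self.absorbing)]


def build_transition_matrix(
    ls: FitnessLandscape, kernel: str = "delta"
) -> TransitionMatrix:
    """Build the SSWM chain for a complete landscape.

    From each non-optimum genotype the probability of stepping to a fitter
    Hamming-1 neighbor is its positive fitness increment normalized over
    all beneficial neighbors (``kernel="delta"``, default) or uniform over
    beneficial neighbors (``kernel="uniform"``).  Local optima are
    absorbing; a genotype with no beneficial neighbor that is not a strict
    optimum (tie plateau) is treated as absorbing with a warning.
    """
    if kernel not in ("delta", "uniform"):
        raise ValueError(f"unknown kernel {kernel!r}")
    n = ls.n_genotypes
    F = ls.fitness
    idx = np.arange(n)
    nbr = idx[:, None] ^ (1 << np.arange(ls.L))[None, :]  # (n, L)
    gain = F[nbr] - F[:, None]
    pos = np.where(gain > 0, gain if kernel == "delta" else 1.0, 0.0)
    tot = pos.sum(axis=1)
    absorbing_mask = tot == 0.0
    strict = np.all(gain < 0, axis=1)
    if np.any(absorbing_mask & ~strict):
        warnings.warn(
            "tie plateau: genotype(s) with no beneficial neighbor but not a "
            "strict optimum are treated as absorbing",
            stacklevel=2,
        )
    P = np.zeros((n, n))
    trans = idx[~absorbing_mask]
    rows = np.repeat(trans, ls.L)
    cols = nbr[trans].ravel()
    vals = (pos[trans] / tot[trans, None]).ravel()
    np.add.at(P, (rows, cols), vals)
    P[absorbing_mask, absorbing_mask.nonzero()[0]] = 1.0
    return TransitionMatrix(P, idx[absorbing_mask], trans)


def absorbing_probabilities(tm: TransitionMatrix) -> np.ndarray:
    """Absorption matrix B: per starting genotype, the probability of
    absorbing at each absorbing state.

    Solves ``(I - Q) B = R`` for transient rows; absorbing rows are unit
    vectors.  Shape (2**L, n_absorbing), columns ordered as
    ``tm.absorbing``.
    """
    n = tm.P.shape[0]
    na = tm.absorbing.size
    B = np.zeros((n, na))
    if tm.transient.size:
        IQ = np.eye(tm.transient.size) - tm.Q
        try:
            Bt = np.linalg.solve(IQ, tm.R)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise ValueError("malformed absorbing chain: singular I - Q") from e
        B[tm.transient] = Bt
    B[tm.absorbing, np.arange(na)] = 1.0
    return B


def sample_sswm_walk(
    tm: TransitionMatrix, start: int, rng: np.random.Generator
) -> list[int]:
    """Sample one adaptive walk from ``start`` until absorption; returns
    the genotype index sequence including both endpoints."""
    absorbing = set(int(a) for a in tm.absorbing)
    path = [int(start)]
    state = int(start)
    while state not in absorbing:
        row = tm.P[state]
        state = int(rng.choice(row.size, p=row))
        path.append(state)
    return path


# ---------------------------------------------------------------------------
# Wright-Fisher on a ring lattice


@dataclass
class WFConfig:
    """Parameters of the ring-lattice Wright-Fisher simulation."""

    npop: int = 500
    mu: float = 1e-3
    r: int = 2
    tmax: int = 2000
    threshold: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.r <= self.npop:
            raise ValueError(f"r={self.r} must lie in [1, npop]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu={self.mu} must lie in [0, 1]")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold={self.threshold} must lie in (0, 1]")
        if self.tmax < 0:
            raise ValueError("tmax must be nonnegative")

    @property
    def well_mixed(self) -> bool:
        return 2 * self.r + 1 >= self.npop


@dataclass
class PopulationTrajectory:
    """Record of one Wright-Fisher run.

    ``occupancy[t, k]`` is the population fraction carrying optimum k (in
    the order of ``optima``) at generation t; ``genotypes``, ``parents``
    and ``mutations`` are populated when lineages are recorded, enabling
    line-of-descent extraction.
    """

    cfg: WFConfig
    optima: np.ndarray  # genotype indices of local optima, Fmax included
    fmax_index: int
    occupancy: np.ndarray  # (T+1, n_optima)
    final_state: np.ndarray
    genotypes: np.ndarray | None = None  # (T+1, npop) when recorded
    parents: np.ndarray | None = None  # (T, npop) parent node of each node
    mutations: list[list[tuple[int, int]]] | None = None  # per-gen (node, site)
    n_generations: int = 0

    @property
    def fmax_occupancy(self) -> np.ndarray:
        k = int(np.where(self.optima == self.fmax_index)[0][0])
        return self.occupancy[:, k]


def _replacement(
    geno: np.ndarray,
    weights: np.ndarray,
    nbr_idx: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synchronous selection+migration sweep; returns parent node per node."""
    npop = geno.size
    if nbr_idx is None:  # panmixia: every node samples from the whole ring
        p = weights / weights.sum()
        return rng.choice(npop, size=npop, p=p)
    W = weights[nbr_idx]  # (npop, 2r+1)
    C = np.cumsum(W, axis=1)
    u = rng.random(npop) * C[:, -1]
    j = (C < u[:, None]).sum(axis=1)
    return nbr_idx[np.arange(npop), j]


def wf_step(
    geno: np.ndarray,
    ls: FitnessLandscape,
    cfg: WFConfig,
    rng: np.random.Generator,
    nbr_idx: np.ndarray | None = None,
    weights_table: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """One generation: replacement by Eq-style softmax over the
    r-neighborhood, then a per-locus mutation sweep.

    Returns (new genotype array, parent node per node, mutation events as
    (node, site) pairs).  ``nbr_idx`` and ``weights_table`` can be
    precomputed for throughput.
    """
    if weights_table is None:
        weights_table = np.exp(ls.fitness - ls.fitness.max())
    if nbr_idx is None and not cfg.well_mixed:
        offs = np.arange(-cfg.r, cfg.r + 1)
        nbr_idx = (np.arange(cfg.npop)[:, None] + offs[None, :]) % cfg.npop
    parents = _replacement(geno, weights_table[geno], nbr_idx, rng)
    new = geno[parents]
    flips = rng.random((cfg.npop, ls.L)) < cfg.mu
    events: list[tuple[int, int]] = []
    if flips.any():
        nodes, sites = np.nonzero(flips)
        new = new.copy()
        for node, site in zip(nodes.tolist(), sites.tolist()):
            new[node] ^= 1 << site
            events.append((node, site))
    return new, parents, events


def wf_simulate(
    ls: FitnessLandscape,
    cfg: WFConfig,
    record_lineage: bool = False,
    stop_at_decision: bool = False,
) -> PopulationTrajectory:
    """Run Wright-Fisher dynamics from an isogenic germline population.

    Tracks per-generation occupancy of every local optimum.  With
    ``stop_at_decision`` the run ends as soon as any optimum's occupancy
    reaches ``cfg.threshold`` (the success criterion is then decided);
    otherwise it runs for ``cfg.tmax`` generations.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    optima = ls.local_optima()
    fmax = ls.global_optimum()
    weights_table = np.exp(ls.fitness - ls.fitness.max())
    nbr_idx = None
    if not cfg.well_mixed:
        offs = np.arange(-cfg.r, cfg.r + 1)
        nbr_idx = (np.arange(cfg.npop)[:, None] + offs[None, :]) % cfg.npop

    geno = np.zeros(cfg.npop, dtype=np.int64)
    occ_rows = [(geno[None, :] == optima[:, None]).mean(axis=1)]
    genotypes = [geno.copy()] if record_lineage else None
    parents_log = [] if record_lineage else None
    mutations_log = [] if record_lineage else None

    t = 0
    for t in range(1, cfg.tmax + 1):
        geno, parents, events = wf_step(
            geno, ls, cfg, rng, nbr_idx=nbr_idx, weights_table=weights_table
        )
        counts = np.bincount(geno, minlength=ls.n_genotypes)
        occ = counts[optima] / cfg.npop
        occ_rows.append(occ)
        if record_lineage:
            genotypes.append(geno.copy())
            parents_log.append(parents)
            mutations_log.append(events)
        if stop_at_decision and np.any(occ >= cfg.threshold):
            break

    return PopulationTrajectory(
        cfg=cfg,
        optima=optima,
        fmax_index=fmax,
        occupancy=np.array(occ_rows),
        final_state=geno,
        genotypes=np.array(genotypes) if record_lineage else None,
        parents=np.array(parents_log) if record_lineage and parents_log else None,
        mutations=mutations_log,
        n_generations=t,
    )


@dataclass
class SuccessRecord:
    replicate: int
    seed: int
    success: bool
    decision_time: int | None  # generation of first threshold crossing
    decided_at: int | None  # genotype index of the deciding optimum


def _decide(traj: PopulationTrajectory, threshold: float) -> SuccessRecord:
    occ = traj.occupancy
    fmax_col = int(np.where(traj.optima == traj.fmax_index)[0][0])
    crossed = occ >= threshold
    any_cross = crossed.any(axis=1)
    if not any_cross.any():
        return SuccessRecord(-1, -1, False, None, None)
    t = int(np.argmax(any_cross))
    winners = np.nonzero(crossed[t])[0]
    # success only if Fmax alone crosses first; ties count as failure
    if winners.size == 1 and winners[0] == fmax_col:
        return SuccessRecord(-1, -1, True, t, traj.fmax_index)
    return SuccessRecord(-1, -1, False, t, int(traj.optima[winners[0]]))


def success_rate(
    ls: FitnessLandscape,
    cfg: WFConfig,
    n_replicates: int,
    master_seed: int | None = None,
    stop_on_first_success: bool = False,
) -> tuple[float, list[SuccessRecord]]:
    """Fraction of replicate populations that enrich the global optimum to
    the occupancy threshold strictly before any local optimum.

    Each replicate uses an independent generator derived from
    ``(master_seed, replicate index)``, so replicate sets are reproducible
    and order-independent.  ``stop_on_first_success`` ends the scan early
    (useful when only "any success" is needed).
    """
    records: list[SuccessRecord] = []
    n_success = 0
    for rep in range(n_replicates):
        seed = np.random.SeedSequence(
            entropy=master_seed if master_seed is not None else 0,
            spawn_key=(rep,),
        ).generate_state(1)[0]
        rep_cfg = WFConfig(
            npop=cfg.npop,
            mu=cfg.mu,
            r=cfg.r,
            tmax=cfg.tmax,
            threshold=cfg.threshold,
            seed=int(seed),
        )
        traj = wf_simulate(ls, rep_cfg, stop_at_decision=True)
        rec = _decide(traj, cfg.threshold)
        rec.replicate = rep
        rec.seed = int(seed)
        records.append(rec)
        n_success += rec.success
        if stop_on_first_success and rec.success:
            break
    return n_success / max(1, len(records)), records


def max_occupancy_profile(traj: PopulationTrajectory) -> dict[int, float]:
    """Maximum occupancy reached by each local optimum over the run,
    keyed by genotype index."""
    peak = traj.occupancy.max(axis=0)
    return {int(g): float(v) for g, v in zip(traj.optima, peak)}
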