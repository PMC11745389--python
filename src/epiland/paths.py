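"""Mutational paths: extraction, weights, entropy and ordering statistics.

A path is the ordered genotype sequence (integer-encoded) from the
germline to a target; consecutive genotypes differ at exactly one site.
Path weights are relative frequencies over an ensemble of replicate
simulations.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .dynamics import PopulationTrajectory, TransitionMatrix, sample_sswm_walk
from .landscape import FitnessLandscape

__all__ = [
    "Path",
    "PathEnsemble",
    "line_of_descent",
    "path_entropy",
    "ordering_probabilities",
    "classify_by_hotspot_step",
    "stepwise_dfe",
    "sample_sswm_paths",
]

Path = tuple[int, ...]


def _validate_path(path: Path) -> None:
    for a, b in zip(path, path[1:]):
        if bin(a ^ b).count("1") != 1:
            raise ValueError(f"consecutive genotypes {a}, {b} are not Hamming-1")


@dataclass
class PathEnsemble:
    """Distinct paths with normalized weights from replicate simulations."""

    paths: list[Path]
    weights: np.ndarray
    n_total: int
    provenance: str = "unspecified"  # e.g. "sswm" | "wf"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.paths) != self.weights.size:
            raise ValueError("paths and weights must align")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.weights.size and not math.isclose(
            float(self.weights.sum()), 1.0, rel_tol=0, abs_tol=1e-9
        ):
            raise ValueError("weights must sum to 1")

    @classmethod
    def from_paths(
        cls, realized: list[Path], provenance: str = "unspecified"
    ) -> "PathEnsemble":
        """Build an ensemble from raw realized paths (one per replicate)."""
        counts = Counter(realized)
        paths = sorted(counts)
        w = np.array([counts[p] for p in paths], dtype=float)
        return cls(paths, w / w.sum(), n_total=len(realized), provenance=provenance)


def line_of_descent(
    traj: PopulationTrajectory, target: int
) -> Path | None:
    """Lineage of the first individual to carry ``target``.

    Follows parent pointers from the first (generation, node) carrying the
    target genotype back to generation 0, reverses, and collapses
    consecutive identical genotypes.  Returns None if the target never
    appears; requires the trajectory to have recorded lineages.
    """
    if traj.genotypes is None or traj.parents is None:
        raise ValueError("trajectory was run without lineage recording")
    hits = np.nonzero(traj.genotypes == target)
    if hits[0].size == 0:
        return None
    t = int(hits[0][0])
    node = int(hits[1][0])
    lineage = [int(traj.genotypes[t, node])]
    while t > 0:
        node = int(traj.parents[t - 1, node])
        t -= 1
        lineage.append(int(traj.genotypes[t, node]))
    lineage.reverse()
    path = [lineage[0]]
    for g in lineage[1:]:
        if g != path[-1]:
            path.append(g)
    _validate_path(tuple(path))
    return tuple(path)


def path_entropy(ens: PathEnsemble) -> float:
    """Gibbs-Shannon entropy of path weights, scaled to [0, 1].

    ``S = -sum_pi w_pi ln w_pi / ln m`` with m the number of distinct
    realized paths; defined as 0 when m == 1.
    """
    w = ens.weights[ens.weights > 0]
    if w.size <= 1:
        return 0.0
    S = -float(np.sum(w * np.log(w)))
    return S / math.log(w.size)


def _forward_event_order(path: Path, L: int) -> dict[int, int]:
    """Step index (1-based, counting forward 0->1 events) of each site's
    first forward mutation along a path."""
    order: dict[int, int] = {}
    step = 0
    for a, b in zip(path, path[1:]):
        site = int(np.log2(a ^ b))
        forward = (b >> site) & 1 == 1
        if forward:
            step += 1
            if site not in order:
                order[site] = step
    return order


def ordering_probabilities(
    ens: PathEnsemble, required_sites: list[int], L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix of probabilities that site i's first forward mutation
    precedes site j's, weight-averaged over paths.

    Paths missing a forward event for any required site are excluded (with
    a warning) and the remaining weights renormalized.  Returns the matrix
    (NaN diagonal, indexed like ``required_sites``) and the flat array of
    off-diagonal entries for histogramming.
    """
    k = len(required_sites)
    M = np.zeros((k, k))
    total_w = 0.0
    dropped = 0
    for path, w in zip(ens.paths, ens.weights):
        order = _forward_event_order(path, L)
        if any(s not in order for s in required_sites):
            dropped += 1
            continue
        total_w += w
        for a, i in enumerate(required_sites):
            for b, j in enumerate(required_sites):
                if a != b and order[i] < order[j]:
                    M[a, b] += w
    if dropped:
        warnings.warn(
            f"{dropped} path(s) missing a required-site event were excluded",
            stacklevel=2,
        )
    if total_w == 0:
        raise ValueError("no path contains all required sites")
    M /= total_w
    np.fill_diagonal(M, np.nan)
    off = M[~np.eye(k, dtype=bool)]
    return M, off


@dataclass
class HotspotClasses:
    """Paths grouped by the step of the hotspot's first forward mutation."""

    classes: dict[int, list[tuple[Path, float]]]
    class_weights: dict[int, float]
    cumulative_weight: list[tuple[int, float]] = field(default_factory=list)


def classify_by_hotspot_step(ens: PathEnsemble, hotspot_site: int, L: int) -> HotspotClasses:
    """Sort paths by the 1-based step at which the hotspot first mutates
    forward; reports per-class paths with weights and the cumulative
    weight across classes."""
    classes: dict[int, list[tuple[Path, float]]] = {}
    for path, w in zip(ens.paths, ens.weights):
        order = _forward_event_order(path, L)
        if hotspot_site not in order:
            raise ValueError("hotspot must mutate in every path of the ensemble")
        classes.setdefault(order[hotspot_site], []).append((path, float(w)))
    class_weights = {
        c: float(sum(w for _, w in members)) for c, members in classes.items()
    }
    cum = []
    acc = 0.0
    for c in sorted(class_weights):
        acc += class_weights[c]
        cum.append((c, acc))
    return HotspotClasses(classes, class_weights, cum)


def stepwise_dfe(
    ens: PathEnsemble, ls: FitnessLandscape
) -> list[list[tuple[float, float]]]:
    """Fitness increments per path step, weighted by path weight.

    Element k is the collection of (delta-F, weight) pairs of the k-th step
    across all paths long enough to take it.
    """
    max_steps = max((len(p) - 1 for p in ens.paths), default=0)
    out: list[list[tuple[float, float]]] = [[] for _ in range(max_steps)]
    for path, w in zip(ens.paths, ens.weights):
        for k, (a, b) in enumerate(zip(path, path[1:])):
            dF = float(ls.fitness[b] - ls.fitness[a])
            out[k].append((dF, float(w)))
    return out


def sample_sswm_paths(
    tm: TransitionMatrix,
    start: int,
    n_walks: int,
    rng: np.random.Generator,
    target: int | None = None,
) -> PathEnsemble:
    """Sample SSWM adaptive walks from ``start`` and build a path ensemble.

    With ``target`` set, only walks absorbing at the target contribute
    (weights renormalized over those); otherwise every walk counts.
    """
    realized: list[Path] = []
    for _ in range(n_walks):
        walk = tuple(sample_sswm_walk(tm, start, rng))
        if target is not None and walk[-1] != target:
            continue
        realized.append(walk)
    if not realized:
        raise ValueError("no sampled walk reached the target")
    return PathEnsemble.from_paths(realized, provenance="sswm")
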