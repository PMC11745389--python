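"""2D embeddings of landscapes and realized paths.

The landscape embedding is a force-directed layout of the hypercube graph
with edge weights inversely related to the fitness difference between
mutational neighbors, ``w = (0.001 + |dF|)**-1``; paths are embedded with
t-SNE on the Hamming-distance matrix.  Layout pairs are compared after a
rigid (rotation + translation, no reflection) alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.manifold import TSNE

from .landscape import FitnessLandscape

__all__ = [
    "EmbeddingLayout",
    "build_similarity_graph",
    "force_directed_layout",
    "align_layouts",
    "tsne_paths",
]

EDGE_EPS = 1e-3


@dataclass
class EmbeddingLayout:
    """2D coordinates per genotype, reproducible given the seed."""

    coords: dict[int, np.ndarray]
    method: str
    seed: int | None = None

    def array(self, nodes: list[int] | None = None) -> np.ndarray:
        nodes = sorted(self.coords) if nodes is None else nodes
        return np.array([self.coords[n] for n in nodes])


def build_similarity_graph(ls: FitnessLandscape) -> nx.Graph:
    """Hypercube graph over all genotypes with fitness-similarity weights.

    Edges join Hamming-1 pairs; weight ``(0.001 + |F(s) - F(s')|)**-1`` so
    similar-fitness neighbors attract in force-directed layouts.
    """
    G = nx.Graph()
    F = ls.fitness
    G.add_nodes_from(range(ls.n_genotypes))
    for s in range(ls.n_genotypes):
        for i in range(ls.L):
            sp = s ^ (1 << i)
            if sp > s:
                w = 1.0 / (EDGE_EPS + abs(F[s] - F[sp]))
                G.add_edge(s, sp, weight=w)
    return G


def force_directed_layout(G: nx.Graph, seed: int = 0) -> EmbeddingLayout:
    """Seeded force-directed (spring) layout of a weighted graph.

    The engine is delegated to networkx's Fruchterman-Reingold
    implementation; the contract is determinism for a fixed seed within a
    run environment, with all landscape-specific content carried by the
    edge weights.
    """
    pos = nx.spring_layout(G, weight="weight", seed=seed)
    coords = {n: np.asarray(xy, dtype=float) for n, xy in pos.items()}
    return EmbeddingLayout(coords, method="force_directed", seed=seed)


def align_layouts(
    A: EmbeddingLayout,
    B: EmbeddingLayout,
    shared: list[int] | None = None,
    allow_reflection: bool = False,
) -> tuple[EmbeddingLayout, float]:
    """Rigidly align layout B onto layout A over the shared node set.

    Solves the 2D orthogonal Procrustes problem restricted to rotations
    (Kabsch with determinant correction); reflections are disallowed by
    default.  Returns the transformed copy of B (all nodes) and the RMS
    residual over shared nodes.
    """
    if shared is None:
        shared = sorted(set(A.coords) & set(B.coords))
    if len(shared) < 2:
        raise ValueError("alignment needs at least 2 shared nodes")
    X = A.array(shared)
    Y = B.array(shared)
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (Y - yc).T @ (X - xc)
    U, _, Vt = np.linalg.svd(H)
    D = np.eye(2)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        D[1, 1] = -1.0
    Rot = U @ D @ Vt
    coords = {
        n: (xy - yc) @ Rot + xc for n, xy in B.coords.items()
    }
    resid = float(
        np.sqrt(np.mean(np.sum((np.array([coords[n] for n in shared]) - X) ** 2, axis=1)))
    )
    return EmbeddingLayout(coords, method=B.method, seed=B.seed), resid


def _hamming_matrix(genotypes: np.ndarray, L: int) -> np.ndarray:
    diff = genotypes[:, None] ^ genotypes[None, :]
    D = np.zeros(diff.shape, dtype=float)
    for i in range(L):
        D += (diff >> i) & 1
    return D


def tsne_paths(
    paths: list[tuple[int, ...]],
    L: int,
    perplexity: float = 10.0,
    seed: int = 0,
) -> EmbeddingLayout:
    """t-SNE embedding of all genotypes visited by a set of paths, using
    Hamming distance as the metric.  Seeded and deterministic within a run
    environment."""
    visited = sorted({g for p in paths for g in p})
    if len(visited) < 3:
        raise ValueError("t-SNE embedding needs at least 3 distinct genotypes")
    genos = np.array(visited)
    D = _hamming_matrix(genos, L)
    perplexity = min(perplexity, (len(visited) - 1) / 3.0)
    ts = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
    )
    Y = ts.fit_transform(D)
    coords = {int(g): np.asarray(Y[k], dtype=float) for k, g in enumerate(visited)}
    return EmbeddingLayout(coords, method="tsne", seed=seed)
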