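"""Louvain–Jaccard subclone identification.

Cells are clustered on their recovered binary genotypes: an exact k-nearest
neighbour graph under Euclidean distance, re-weighted by the Jaccard
similarity of neighbour sets (shared-nearest-neighbour weighting), then
Louvain modularity optimisation.  The number of subclones is not specified
in advance — it falls out of the community structure.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class ClusterConfig:
    k_neighbors: int = 20
    resolution: float = 1.0
    seed: int = 0
    min_cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.min_cluster_size < 0:
            raise ValueError("min_cluster_size must be >= 0")


@dataclass
class SubcloneAssignment:
    """Per-cell subclone labels in [0, K), label 0 being the largest cluster."""

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if self.K < 1 or not np.array_equal(present, np.arange(self.K)):
            raise ValueError(
                f"labels must use every integer in [0, {self.K}) at least once"
            )

    @property
    def n(self) -> int:
        return len(self.labels)


def knn_graph(G: np.ndarray, k: int) -> list[frozenset[int]]:
    """Exact k nearest neighbours of each cell under Euclidean row distance.

    Ties are broken by lower cell index so the graph is deterministic.
    k is clamped to n−1 with a warning.
    """
    G = np.asarray(G, dtype=np.float64)
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if k >= n:
        warnings.warn(
            f"k_neighbors={k} >= n={n}; clamped to {n - 1}", stacklevel=2
        )
        k = n - 1
    D = cdist(G, G)
    np.fill_diagonal(D, np.inf)  # a cell is not its own neighbour
    neighbors = []
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, D[i]))  # distance first, index breaks ties
        neighbors.append(frozenset(int(j) for j in order[:k]))
    return neighbors


def jaccard_weights(
    neighbors: list[frozenset[int]],
) -> list[tuple[int, int, float]]:
    """Shared-nearest-neighbour edges: weight = |N(i)∩N(j)| / |N(i)∪N(j)|.

    An edge is considered for every pair adjacent in the kNN graph (either
    direction); zero-weight edges are dropped.
    """
    n = len(neighbors)
    pairs = set()
    for i in range(n):
        for j in neighbors[i]:
            pairs.add((min(i, j), max(i, j)))
    edges = []
    for i, j in sorted(pairs):
        inter = len(neighbors[i] & neighbors[j])
        if inter == 0:
            continue
        union = len(neighbors[i] | neighbors[j])
        edges.append((i, j, inter / union))
    return edges


def _renumber_by_size(labels: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, counts = np.unique(labels, return_counts=True)
    # biggest first; equal sizes keep their original label order
    order = np.lexsort((uniq, -counts))
    mapping = {int(old): new for new, old in enumerate(uniq[order])}
    return np.array([mapping[int(l)] for l in labels]), len(uniq)


def _merge_small_clusters(
    labels: np.ndarray, genotypes: np.ndarray, min_size: int
) -> np.ndarray:
    """Fold clusters below min_size into the nearest large cluster.

    Nearest = smallest Euclidean distance between consensus (per-site
    majority) genotypes.
    """
    labels = labels.copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        small = uniq[counts < min_size]
        large = uniq[counts >= min_size]
        if len(small) == 0 or len(large) == 0 or len(uniq) == 1:
            return labels
        consensus = {
            int(l): (genotypes[labels == l].mean(axis=0) > 0.5).astype(float)
            for l in uniq
        }
        # merge the smallest offender first
        l_small = int(small[np.argmin(counts[np.isin(uniq, small)])])
        d = [
            (float(np.linalg.norm(consensus[l_small] - consensus[int(l)])), int(l))
            for l in large
        ]
        _, target = min(d)
        labels[labels == l_small] = target


def louvain_cluster(
    edges: list[tuple[int, int, float]],
    cfg: ClusterConfig,
    n_cells: int,
    genotypes: np.ndarray | None = None,
) -> SubcloneAssignment:
    """Louvain modularity communities on the weighted Jaccard graph.

    Node order is shuffled by the seed and igraph's RNG is seeded, so the
    partition is reproducible.  Clusters smaller than min_cluster_size are
    merged into the nearest cluster by consensus-genotype distance (requires
    ``genotypes``); labels are renumbered by decreasing cluster size.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not edges:
        warnings.warn(
            "empty edge list: every cell becomes its own cluster", stacklevel=2
        )
        return SubcloneAssignment(labels=np.arange(n_cells), K=n_cells)

    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x10])
    perm = rng.permutation(n_cells)  # position of each original node
    inv = np.argsort(perm)
    g = igraph.Graph(n=n_cells)
    g.add_edges([(int(perm[i]), int(perm[j])) for i, j, _ in edges])
    g.es["weight"] = [w for _, _, w in edges]

    random.seed(cfg.seed & 0x7FFFFFFF)  # igraph delegates to Python's RNG
    part = g.community_multilevel(weights="weight", resolution=cfg.resolution)
    labels = np.asarray(part.membership)[perm]

    if cfg.min_cluster_size > 1:
        if genotypes is None:
            raise ValueError(
                "min_cluster_size > 1 requires the genotype matrix"
            )
        labels = _merge_small_clusters(labels, np.asarray(genotypes, float),
                                       cfg.min_cluster_size)

    labels, K = _renumber_by_size(labels)
    return SubcloneAssignment(labels=labels, K=K)


def cluster_cells(
    G: np.ndarray, cfg: ClusterConfig | None = None
) -> SubcloneAssignment:
    """kNN → Jaccard → Louvain on a binary genotype-call matrix."""
    cfg = cfg or ClusterConfig()
    neighbors = knn_graph(G, cfg.k_neighbors)
    edges = jaccard_weights(neighbors)
    return louvain_cluster(edges, cfg, n_cells=len(neighbors), genotypes=G)
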