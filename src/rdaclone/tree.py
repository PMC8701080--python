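"""Subclone evolutionary tree from consensus genotypes.

Each subclone's genotype is the per-site majority call among its member
cells (ties resolve to 0, the ancestral state).  The clonal tree is the
minimum spanning tree of pairwise Euclidean distances between consensus
genotypes, rooted at the subclone with the fewest mutations — the
most-normal genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .clustering import SubcloneAssignment


@dataclass
class SubcloneTree:
    consensus: np.ndarray                      # K×m binary
    edges: list[tuple[int, int, float]]        # (parent, child, weight)
    root: int
    newick: str


def consensus_genotypes(G: np.ndarray, a: SubcloneAssignment) -> np.ndarray:
    """Per-subclone, per-site majority genotype; exact ties resolve to 0."""
    G = np.asarray(G)
    if G.shape[0] != a.n:
        raise ValueError("genotype rows and label count differ")
    out = np.empty((a.K, G.shape[1]), dtype=np.int8)
    for k in range(a.K):
        members = G[a.labels == k]
        if members.shape[0] == 0:
            raise ValueError(f"subclone {k} has no member cells")
        # strict majority of 1s; a 50/50 tie stays 0
        out[k] = (members.mean(axis=0) > 0.5).astype(np.int8)
    return out


def subclone_distances(consensus: np.ndarray) -> np.ndarray:
    """K×K symmetric Euclidean distance matrix between consensus rows."""
    consensus = np.asarray(consensus, dtype=np.float64)
    if consensus.ndim != 2 or consensus.shape[0] < 1:
        raise ValueError("need a K×m consensus matrix with K >= 1")
    if consensus.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(consensus, metric="euclidean"))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(D: np.ndarray) -> list[tuple[int, int, float]]:
    """Kruskal MST of a distance matrix.

    Equal-weight edges are taken in lexicographic (a, b) order, so the tree
    is deterministic — ties are common on binary genotypes.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.size == 0:
        raise ValueError("empty distance matrix")
    K = D.shape[0]
    if D.shape != (K, K):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any() or not np.allclose(np.diag(D), 0):
        raise ValueError("distances must be non-negative with zero diagonal")
    if K == 1:
        return []
    candidates = sorted(
        ((float(D[a, b]), a, b) for a in range(K) for b in range(a + 1, K)),
    )
    uf = _UnionFind(K)
    edges = []
    for w, a, b in candidates:
        if uf.union(a, b):
            edges.append((a, b, w))
            if len(edges) == K - 1:
                break
    return edges


def _orient_edges(
    edges: list[tuple[int, int, float]], root: int, K: int
) -> tuple[list[tuple[int, int, float]], dict[int, list[tuple[int, float]]]]:
    adj: dict[int, list[tuple[int, float]]] = {k: [] for k in range(K)}
    for a, b, w in edges:
        adj[a].append((b, w))
        adj[b].append((a, w))
    oriented = []
    children: dict[int, list[tuple[int, float]]] = {k: [] for k in range(K)}
    stack, seen = [root], {root}
    while stack:
        u = stack.pop()
        for v, w in sorted(adj[u]):
            if v not in seen:
                seen.add(v)
                oriented.append((u, v, w))
                children[u].append((v, w))
                stack.append(v)
    if len(seen) != K:
        raise ValueError("edges do not form a spanning tree")
    return oriented, children


def _newick(node: int, children: dict[int, list[tuple[int, float]]]) -> str:
    kids = children[node]
    label = f"subclone_{node}"
    if not kids:
        return label
    inner = ",".join(
        f"{_newick(v, children)}:{w:.9g}" for v, w in sorted(kids)
    )
    return f"({inner}){label}"


def root_tree(
    edges: list[tuple[int, int, float]], consensus: np.ndarray
) -> SubcloneTree:
    """Root the MST at the minimum-mutation-burden subclone and serialise it.

    The root is the most-normal genotype (fewest 1s; ties → lowest label);
    edges are re-oriented away from it and written as Newick with the MST
    Euclidean weights as branch lengths.
    """
    consensus = np.asarray(consensus)
    K = consensus.shape[0]
    burden = consensus.sum(axis=1)
    root = int(np.argmin(burden))  # argmin takes the lowest index on ties
    if K == 1:
        return SubcloneTree(
            consensus=consensus, edges=[], root=0, newick="subclone_0;"
        )
    oriented, children = _orient_edges(edges, root, K)
    newick = _newick(root, children) + ";"
    return SubcloneTree(
        consensus=consensus, edges=oriented, root=root, newick=newick
    )


def build_tree(G: np.ndarray, a: SubcloneAssignment) -> SubcloneTree:
    """consensus → distances → MST → rooted tree, in one call."""
    cons = consensus_genotypes(G, a)
    D = subclone_distances(cons)
    edges = minimum_spanning_tree(D)
    return root_tree(edges, cons)
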