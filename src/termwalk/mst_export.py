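"""Minimum spanning tree over the term-term distance matrix.

The MST sketches the global backbone of term relationships: the n-1
smallest distances that keep every term connected without cycles.
Construction is Kruskal's algorithm with a deterministic tie-break —
edges sort by (weight, term_a, term_b) with term_a < term_b
lexicographically — written out directly (union-find) because the
tie-break is part of the contract.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = ["TermTree", "minimum_spanning_tree", "export_tree",
           "read_tree_graphml"]


@dataclass
class TermTree:
    """A spanning tree over terms: exactly ``n_terms - 1`` weighted edges."""

    edges: List[Tuple[str, str, float]]
    n_terms: int

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


class _UnionFind:
    def __init__(self, n: int) -> None:
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
        self.parent[ra] = rb
        return True


def minimum_spanning_tree(
    distance_matrix: np.ndarray, term_ids: Sequence[str]
) -> TermTree:
    """Kruskal MST of a symmetric, finite, zero-diagonal distance matrix.

    Edge endpoints are reported with ``term_a < term_b``; among equal
    weights the lexicographically smallest (term_a, term_b) wins.
    """
    mat = np.asarray(distance_matrix, dtype=np.float64)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 terms for a spanning tree")
    if mat.shape != (n, n) or len(term_ids) != n:
        raise ValueError("matrix shape and term_ids disagree")
    if not np.all(np.isfinite(mat)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix is not symmetric")
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = term_ids[i], term_ids[j]
            if b < a:
                a, b = b, a
            candidates.append((mat[i, j], a, b, i, j))
    candidates.sort(key=lambda e: (e[0], e[1], e[2]))
    uf = _UnionFind(n)
    edges: List[Tuple[str, str, float]] = []
    for w, a, b, i, j in candidates:
        if uf.union(i, j):
            edges.append((a, b, float(w)))
            if len(edges) == n - 1:
                break
    return TermTree(edges=edges, n_terms=n)


def export_tree(
    tree: TermTree,
    tsv_path: os.PathLike | str | None = None,
    graphml_path: os.PathLike | str | None = None,
) -> None:
    """Write the tree as an edge-list TSV and/or GraphML (weight attribute)."""
    if not tree.edges:
        raise ValueError("refusing to export an edgeless tree")
    if tsv_path is None and graphml_path is None:
        raise ValueError("no output path given")
    if tsv_path is not None:
        with open(tsv_path, "w", encoding="utf-8") as handle:
            handle.write("term_a\tterm_b\tweight\n")
            for a, b, w in tree.edges:
                handle.write(f"{a}\t{b}\t{w!r}\n")
    if graphml_path is not None:
        g = nx.Graph()
        for a, b, w in tree.edges:
            g.add_edge(a, b, weight=float(w))
        nx.write_graphml(g, graphml_path)


def read_tree_graphml(path: os.PathLike | str) -> TermTree:
    """Load a tree previously written by :func:`export_tree`."""
    g = nx.read_graphml(path)
    edges = []
    for a, b, data in g.edges(data=True):
        x, y = (a, b) if a < b else (b, a)
        edges.append((x, y, float(data["weight"])))
    edges.sort()
    return TermTree(edges=edges, n_terms=g.number_of_nodes())
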