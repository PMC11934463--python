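"""Indexed gene-term bipartite graph construction.

Genes occupy indices ``0..m-1`` (first-appearance order over the collection)
and terms occupy ``m..m+n-1`` (file order), so the node universe has exactly
``m + n`` nodes.  Edges join a gene index to a term index; the graph is
undirected for walk purposes but the edge set is stored once as
``(gene_index, term_index)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np

from .gmt_io import GeneSetCollection

__all__ = ["NodeIndex", "BipartiteGraph", "build_index", "build_graph",
           "neighbors", "export_graph_tables"]


@dataclass(frozen=True)
class NodeIndex:
    """Bijections gene symbol -> {0..m-1} and term_id -> {m..m+n-1}."""

    gene_to_index: Dict[str, int]
    term_to_index: Dict[str, int]

    @property
    def m(self) -> int:
        return len(self.gene_to_index)

    @property
    def n(self) -> int:
        return len(self.term_to_index)

    @property
    def n_nodes(self) -> int:
        return self.m + self.n

    def is_gene(self, node: int) -> bool:
        self._check(node)
        return node < self.m

    def name_of(self, node: int) -> str:
        self._check(node)
        if node < self.m:
            return self.gene_symbols[node]
        return self.term_ids[node - self.m]

    @property
    def gene_symbols(self) -> List[str]:
        out = [""] * self.m
        for g, i in self.gene_to_index.items():
            out[i] = g
        return out

    @property
    def term_ids(self) -> List[str]:
        out = [""] * self.n
        for t, i in self.term_to_index.items():
            out[i - self.m] = t
        return out

    def _check(self, node: int) -> None:
        if not (0 <= node < self.n_nodes):
            raise IndexError(f"node {node} outside universe 0..{self.n_nodes - 1}")


def build_index(collection: GeneSetCollection) -> NodeIndex:
    """Assign node indices: genes by first appearance, terms by file order."""
    if len(collection) == 0:
        raise ValueError("cannot index an empty collection")
    gene_to_index: Dict[str, int] = {}
    for record in collection:
        for gene in sorted(record.genes):
            if gene not in gene_to_index:
                gene_to_index[gene] = len(gene_to_index)
    m = len(gene_to_index)
    term_to_index = {t.term_id: m + j for j, t in enumerate(collection)}
    return NodeIndex(gene_to_index, term_to_index)


@dataclass
class BipartiteGraph:
    """The indexed gene-term graph ``Graph = (V, E)``, ``|V| = m + n``."""

    index: NodeIndex
    edges: Set[Tuple[int, int]]
    _adjacency: Tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_nodes(self) -> int:
        return self.index.n_nodes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_csr(self) -> Tuple[np.ndarray, np.ndarray]:
        """Sorted CSR adjacency ``(indptr, indices)`` over the full undirected
        node universe; built once and cached."""
        if self._adjacency is None:
            nv = self.n_nodes
            deg = np.zeros(nv, dtype=np.int64)
            for g, t in self.edges:
                deg[g] += 1
                deg[t] += 1
            indptr = np.zeros(nv + 1, dtype=np.int64)
            np.cumsum(deg, out=indptr[1:])
            indices = np.empty(indptr[-1], dtype=np.int64)
            cursor = indptr[:-1].copy()
            for g, t in sorted(self.edges):
                indices[cursor[g]] = t
                cursor[g] += 1
                indices[cursor[t]] = g
                cursor[t] += 1
            for v in range(nv):
                indices[indptr[v]:indptr[v + 1]].sort()
            self._adjacency = (indptr, indices)
        return self._adjacency

    def degree(self, node: int) -> int:
        indptr, _ = self.adjacency_csr()
        self.index._check(node)
        return int(indptr[node + 1] - indptr[node])


def build_graph(collection: GeneSetCollection, index: NodeIndex) -> BipartiteGraph:
    """Add one edge per (gene, term) membership pair.

    The edge count equals the sum of (deduplicated) gene-set sizes.  Raises
    if the collection mentions a gene or term the index does not know.
    """
    edges: Set[Tuple[int, int]] = set()
    for record in collection:
        if record.term_id not in index.term_to_index:
            raise KeyError(f"term {record.term_id!r} missing from index")
        t = index.term_to_index[record.term_id]
        for gene in record.genes:
            if gene not in index.gene_to_index:
                raise KeyError(f"gene {gene!r} missing from index")
            edges.add((index.gene_to_index[gene], t))
    return BipartiteGraph(index, edges)


def neighbors(graph: BipartiteGraph, node: int) -> List[int]:
    """Sorted, duplicate-free adjacency of ``node`` (genes give terms and
    vice versa)."""
    graph.index._check(node)
    indptr, indices = graph.adjacency_csr()
    return indices[indptr[node]:indptr[node + 1]].tolist()


def export_graph_tables(
    graph: BipartiteGraph, edge_path: os.PathLike | str,
    node_path: os.PathLike | str,
) -> None:
    """Write the edge list (2-column TSV of indices) and the node table
    (index, name, partition)."""
    with open(edge_path, "w", encoding="utf-8") as handle:
        handle.write("gene_index\tterm_index\n")
        for g, t in sorted(graph.edges):
            handle.write(f"{g}\t{t}\n")
    index = graph.index
    with open(node_path, "w", encoding="utf-8") as handle:
        handle.write("index\tname\tpartition\n")
        for i in range(index.n_nodes):
            part = "gene" if i < index.m else "term"
            handle.write(f"{i}\t{index.name_of(i)}\t{part}\n")
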