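"""Cross-species projection into a frozen host embedding space.

A second-species collection is first ortholog-converted into the host
symbol namespace (every gene replaced by all of its ortholog targets;
unmapped genes dropped, emptied terms dropped with a report).  Converted
terms are then placed in the pre-trained host space by one of two
strategies:

``neighbor_mean``
    the term vector is the arithmetic mean of the host vectors of its
    mapped genes — deterministic and training-free (default);
``frozen_training``
    the host graph is extended with the foreign term nodes, biased walks
    are started from them, and skip-gram updates are applied to the new
    rows only, the host vectors acting as fixed context targets.

Either way the host embedding is bit-unchanged, so nearest-neighbor
queries against host terms are comparable across projections.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .gmt_io import GeneSetCollection, OrthologMap, TermRecord
from .graph_build import BipartiteGraph, NodeIndex
from .node2vec_core import (
    DEFAULT_CONFIG,
    EmbeddingMatrix,
    WalkConfig,
    _derive_seed,
    _noise_table,
)

__all__ = [
    "ConversionResult",
    "ProjectedTerms",
    "convert_collection",
    "project_terms",
    "nearest_terms",
]


@dataclass
class ConversionResult:
    """Ortholog-converted collection plus the mandatory attrition report."""

    collection: GeneSetCollection
    dropped_terms: List[str]
    unmapped_genes: Set[str]
    report: pd.DataFrame  # term_id, n_genes, n_mapped, coverage, status


@dataclass
class ProjectedTerms:
    """Vectors for foreign terms living in the host embedding space."""

    vectors: Dict[str, np.ndarray]
    strategy: str
    coverage: Dict[str, float]
    d: int

    def save_tsv(self, path: os.PathLike | str, species_label: str = "") -> None:
        with open(path, "w", encoding="utf-8") as handle:
            cols = "\t".join(f"v{i + 1}" for i in range(self.d))
            handle.write(f"term_id\tspecies\tstrategy\tcoverage\t{cols}\n")
            for term_id in sorted(self.vectors):
                vals = "\t".join(repr(float(x)) for x in self.vectors[term_id])
                handle.write(
                    f"{term_id}\t{species_label}\t{self.strategy}\t"
                    f"{float(self.coverage[term_id])!r}\t{vals}\n"
                )


def convert_collection(
    collection: GeneSetCollection, orthologs: OrthologMap
) -> ConversionResult:
    """Replace each gene by all of its ortholog targets.

    One-to-many sources fan out to every target; many-to-one targets
    collapse by set semantics.  Terms with no mapped gene are dropped (and
    listed), never fatal.
    """
    mapping = orthologs.as_dict()
    kept: List[TermRecord] = []
    dropped: List[str] = []
    unmapped: Set[str] = set()
    report_rows = []
    for record in collection:
        converted: Set[str] = set()
        n_mapped = 0
        for gene in record.genes:
            targets = mapping.get(gene)
            if targets:
                converted |= targets
                n_mapped += 1
            else:
                unmapped.add(gene)
        coverage = n_mapped / len(record.genes)
        if converted:
            kept.append(TermRecord(record.term_id, record.description,
                                   frozenset(converted)))
            status = "kept"
        else:
            dropped.append(record.term_id)
            status = "dropped"
        report_rows.append((record.term_id, len(record.genes), n_mapped,
                            coverage, status))
    report = pd.DataFrame(
        report_rows,
        columns=["term_id", "n_genes", "n_mapped", "coverage", "status"],
    )
    converted_collection = GeneSetCollection(
        kept, species_label=f"{collection.species_label}->host".strip("->"),
    )
    return ConversionResult(converted_collection, dropped, unmapped, report)


def project_terms(
    converted: GeneSetCollection,
    host_graph: BipartiteGraph,
    host_embeddings: EmbeddingMatrix,
    strategy: str = "neighbor_mean",
    config: Optional[WalkConfig] = None,
) -> Tuple[ProjectedTerms, pd.DataFrame]:
    """Place converted foreign terms in the host space.

    Returns the projection and a per-term report (term_id, n_genes,
    n_mapped, coverage, status); terms with no gene present among host
    gene nodes are dropped with status ``dropped``.  The host embedding
    matrix is never written to.
    """
    if strategy not in ("neighbor_mean", "frozen_training"):
        raise ValueError(f"unknown strategy {strategy!r}")
    index = host_graph.index
    mapped: Dict[str, List[int]] = {}
    report_rows = []
    for record in converted:
        gene_nodes = [index.gene_to_index[g] for g in record.genes
                      if g in index.gene_to_index]
        coverage = len(gene_nodes) / len(record.genes)
        status = "projected" if gene_nodes else "dropped"
        report_rows.append((record.term_id, len(record.genes),
                            len(gene_nodes), coverage, status))
        if gene_nodes:
            mapped[record.term_id] = sorted(gene_nodes)
    report = pd.DataFrame(
        report_rows,
        columns=["term_id", "n_genes", "n_mapped", "coverage", "status"],
    )
    coverage_by_term = {
        row[0]: row[3] for row in report_rows if row[4] == "projected"
    }
    if strategy == "neighbor_mean":
        vectors = {
            term_id: host_embeddings.vectors[nodes].mean(axis=0)
            for term_id, nodes in mapped.items()
        }
    else:
        vectors = _frozen_training_vectors(
            mapped, host_graph, host_embeddings,
            config if config is not None else DEFAULT_CONFIG,
        )
    projected = ProjectedTerms(
        vectors=vectors,
        strategy=strategy,
        coverage=coverage_by_term,
        d=host_embeddings.d,
    )
    return projected, report


def _frozen_training_vectors(
    mapped: Dict[str, List[int]],
    host_graph: BipartiteGraph,
    host_embeddings: EmbeddingMatrix,
    config: WalkConfig,
) -> Dict[str, np.ndarray]:
    """Extend the graph with foreign term nodes and train only their rows."""
    nv = host_graph.n_nodes
    term_ids = sorted(mapped)
    n_foreign = len(term_ids)
    if n_foreign == 0:
        return {}
    # extended CSR: host edges plus (gene, foreign-term) edges
    extra_edges = [
        (g, nv + fi) for fi, term_id in enumerate(term_ids)
        for g in mapped[term_id]
    ]
    total = nv + n_foreign
    deg = np.zeros(total, dtype=np.int64)
    host_indptr, host_indices = host_graph.adjacency_csr()
    deg[:nv] = np.diff(host_indptr)
    for g, f in extra_edges:
        deg[g] += 1
        deg[f] += 1
    indptr = np.zeros(total + 1, dtype=np.int64)
    np.cumsum(deg, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    cursor = indptr[:-1].copy()
    for v in range(nv):
        nb = host_indices[host_indptr[v]:host_indptr[v + 1]]
        indices[cursor[v]:cursor[v] + nb.size] = nb
        cursor[v] += nb.size
    for g, f in extra_edges:
        indices[cursor[g]] = f
        cursor[g] += 1
        indices[cursor[f]] = g
        cursor[f] += 1
    for v in range(total):
        indices[indptr[v]:indptr[v + 1]].sort()
    # walks start from foreign term nodes only
    rng = np.random.default_rng(_derive_seed(config.seed, 11))
    starts = np.concatenate(
        [rng.permutation(np.arange(nv, total, dtype=np.int64))
         for _ in range(config.walks_per_node)]
    )
    walks = _kernels.simulate_walks_kernel(
        indptr, indices, starts, config.walk_length,
        float(config.p), float(config.q), _derive_seed(config.seed, 12),
    )
    d = host_embeddings.d
    if config.dimensions != d:
        raise ValueError(
            f"config.dimensions={config.dimensions} does not match host d={d}"
        )
    rng2 = np.random.default_rng(_derive_seed(config.seed, 13))
    syn0 = np.empty((total, d), dtype=np.float64)
    syn0[:nv] = host_embeddings.vectors
    syn0[nv:] = (rng2.random((n_foreign, d)) - 0.5) / d
    host_before = host_embeddings.vectors.copy()
    table = _noise_table(walks, total)
    _kernels.sgns_project_kernel(
        walks, syn0, nv, table, config.context_size,
        config.negative_samples, config.epochs, 0.025, 1e-4,
        _derive_seed(config.seed, 14),
    )
    # frozen contract: host rows must be bitwise untouched
    assert np.array_equal(syn0[:nv], host_before)
    return {term_id: syn0[nv + fi].copy()
            for fi, term_id in enumerate(term_ids)}


def nearest_terms(
    query: np.ndarray,
    host_embeddings: EmbeddingMatrix,
    index: NodeIndex,
    k: int,
) -> List[Tuple[str, float]]:
    """k nearest host TERM nodes to ``query`` by euclidean distance,
    ascending, ties broken by term_id; k beyond the term count returns
    every term."""
    if k < 1:
        raise ValueError("k must be >= 1")
    query = np.asarray(query, dtype=np.float64)
    term_vecs = host_embeddings.term_matrix(index)
    dists = np.sqrt(((term_vecs - query) ** 2).sum(axis=1))
    term_ids = index.term_ids
    order = sorted(range(index.n), key=lambda i: (dists[i], term_ids[i]))
    return [(term_ids[i], float(dists[i])) for i in order[:k]]
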