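"""Term-pair statistics: Jaccard, hypergeometric significance, distances.

For two terms with gene sets A and B the Jaccard index is
``J = |A ∩ B| / |A ∪ B|``.  Overlap significance is the hypergeometric
upper tail ``P(X >= k)`` for ``k`` shared genes when ``|B|`` genes are
drawn without replacement from a universe of ``N`` genes of which ``|A|``
are "successes" (the conventional gene-set over-representation screen,
used at p < 0.05).  Embedding distances are euclidean by default (cosine
selectable), min-max normalized to [0, 1] globally over all pairs of a
run, and thresholded at the closest ``fraction`` (top 5% by default
elsewhere in the pipeline).
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .graph_build import BipartiteGraph, NodeIndex
from .node2vec_core import EmbeddingMatrix

__all__ = [
    "jaccard_index",
    "hypergeometric_pvalue",
    "pairwise_term_distances",
    "minmax_normalize",
    "top_fraction_threshold",
    "build_pair_table",
    "write_pair_table",
]

PAIR_TABLE_COLUMNS = [
    "term_a", "term_b", "jaccard", "hypergeom_p",
    "raw_distance", "norm_distance", "rs",
]


def jaccard_index(set_a: Set[str], set_b: Set[str]) -> float:
    """``|A ∩ B| / |A ∪ B|``; 1 iff the sets are equal, 0 iff disjoint."""
    if not set_a or not set_b:
        raise ValueError("Jaccard index requires two non-empty sets")
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    return inter / union


def hypergeometric_pvalue(k: int, size_a: int, size_b: int, universe: int) -> float:
    """Upper-tail overlap probability ``P(X >= k)``.

    ``X`` is hypergeometric with population ``universe``, ``size_a``
    successes and ``size_b`` draws.  ``k = 0`` gives exactly 1.
    """
    if not (0 <= k <= min(size_a, size_b)):
        raise ValueError(f"overlap k={k} inconsistent with set sizes "
                         f"{size_a}, {size_b}")
    if max(size_a, size_b) > universe:
        raise ValueError("set size exceeds universe")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe, size_a, size_b))


def pairwise_term_distances(
    embeddings: EmbeddingMatrix, index: NodeIndex, metric: str = "euclidean"
) -> np.ndarray:
    """Symmetric zero-diagonal (n x n) distance matrix over term nodes,
    in term-index order."""
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric {metric!r}")
    points = embeddings.term_matrix(index)
    if points.shape[0] != index.n:
        raise ValueError("embedding is missing term vectors")
    mat = squareform(pdist(points, metric=metric))
    np.fill_diagonal(mat, 0.0)
    # cosine distance can go fractionally negative from rounding
    return np.maximum(mat, 0.0)


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """``(x - min) / (max - min)`` onto [0, 1]; a constant input maps to
    all zeros."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty sequence")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def top_fraction_threshold(distances: Sequence[float], fraction: float) -> float:
    """Distance value below (or at) which the closest ``fraction`` of
    pairs lies: the ``ceil(fraction * N)``-th smallest value."""
    arr = np.sort(np.asarray(distances, dtype=np.float64))
    if arr.size == 0:
        raise ValueError("empty distance sequence")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rank = math.ceil(fraction * arr.size)
    return float(arr[rank - 1])


def build_pair_table(
    collection,
    graph: BipartiteGraph,
    embeddings: EmbeddingMatrix,
    metric: str = "euclidean",
    universe: Optional[int] = None,
    adjust_pvalues: bool = False,
) -> pd.DataFrame:
    """One row per unordered term pair with all three statistics.

    The hypergeometric universe defaults to the number of distinct genes in
    the graph.  ``norm_distance`` is the global min-max normalization of
    ``raw_distance`` over all pairs in the table.  With ``adjust_pvalues``
    a Benjamini-Hochberg column ``hypergeom_q`` is appended (off by
    default; the screening convention is the raw p < 0.05).
    """
    index = graph.index
    n = index.n
    if universe is None:
        universe = index.m
    gene_sets = {t.term_id: t.genes for t in collection}
    dist = pairwise_term_distances(embeddings, index, metric=metric)
    term_ids = index.term_ids
    rows = []
    for i in range(n):
        genes_i = gene_sets[term_ids[i]]
        for j in range(i + 1, n):
            genes_j = gene_sets[term_ids[j]]
            k = len(genes_i & genes_j)
            rows.append((
                term_ids[i], term_ids[j],
                jaccard_index(genes_i, genes_j),
                hypergeometric_pvalue(k, len(genes_i), len(genes_j), universe),
                dist[i, j],
            ))
    table = pd.DataFrame(
        rows, columns=["term_a", "term_b", "jaccard", "hypergeom_p",
                       "raw_distance"],
    )
    table["norm_distance"] = minmax_normalize(table["raw_distance"].to_numpy())
    table["rs"] = pd.array([pd.NA] * len(table), dtype="Int64")
    if adjust_pvalues:
        table["hypergeom_q"] = stats.false_discovery_control(
            table["hypergeom_p"].to_numpy(), method="bh"
        )
    return table


def write_pair_table(table: pd.DataFrame, path: os.PathLike | str) -> None:
    """TSV export; unannotated ``rs`` cells are left empty."""
    table.to_csv(path, sep="\t", index=False, na_rep="")
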