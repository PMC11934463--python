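"""k-means and internal clustering validation for embedding selection.

Embedding quality is judged without labels: k-means partitions the
vectors, then the Silhouette score
``S = (1/n) Σ_i (b_i - a_i) / max(a_i, b_i)``
(higher is better; a_i = mean distance to own-cluster co-members, b_i =
smallest mean distance to another cluster, singleton s_i = 0) and the
Davies-Bouldin score
``DB = (1/k) Σ_i max_{j≠i} (σ_i + σ_j) / d(c_i, c_j)``
(lower is better; σ_i = mean distance of cluster i's points to its
centroid c_i) summarize cohesion and separation.  Both use euclidean
distance, matching the embedding space.  Hyperparameter configurations
are ranked by Silhouette descending with Davies-Bouldin ascending as the
tiebreak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics
from sklearn.cluster import KMeans

from .graph_build import NodeIndex
from .node2vec_core import EmbeddingMatrix, WalkConfig

__all__ = [
    "ClusteringResult",
    "kmeans",
    "silhouette_score",
    "davies_bouldin_score",
    "evaluate_embedding",
    "select_hyperparameters",
    "grid_report",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    centroids: np.ndarray
    silhouette: float
    davies_bouldin: float


def kmeans(points: np.ndarray, k: int, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Lloyd's k-means with seeded initialization; returns (labels, centroids)."""
    points = np.asarray(points, dtype=np.float64)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > points.shape[0]:
        raise ValueError(f"k={k} exceeds number of points {points.shape[0]}")
    model = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = model.fit_predict(points)
    return labels, model.cluster_centers_


def _check_labels(points: np.ndarray, labels: np.ndarray) -> int:
    if points.shape[0] != labels.shape[0]:
        raise ValueError("points and labels disagree in length")
    n_clusters = np.unique(labels).size
    if n_clusters < 2:
        raise ValueError("at least 2 clusters are required")
    return n_clusters


def silhouette_score(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over points, euclidean; always in [-1, 1]."""
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    n_clusters = _check_labels(points, labels)
    if n_clusters == points.shape[0]:
        return 0.0  # every cluster a singleton: s_i = 0 by convention
    return float(_skmetrics.silhouette_score(points, labels, metric="euclidean"))


def davies_bouldin_score(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean worst-case cluster-similarity ratio; 0 when clusters are
    point-like and far apart.  Raises on coincident centroids (the ratio
    is undefined)."""
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    _check_labels(points, labels)
    uniq = np.unique(labels)
    centroids = np.stack([points[labels == c].mean(axis=0) for c in uniq])
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            if np.allclose(centroids[i], centroids[j]):
                raise ValueError(
                    f"clusters {uniq[i]} and {uniq[j]} have coincident centroids"
                )
    return float(_skmetrics.davies_bouldin_score(points, labels))


def evaluate_embedding(
    embeddings: EmbeddingMatrix,
    index: NodeIndex,
    k: int,
    seed: int = 0,
    nodes: str = "terms",
) -> ClusteringResult:
    """Cluster term vectors (or all node vectors) and score the partition."""
    if nodes == "terms":
        points = embeddings.term_matrix(index)
    elif nodes == "all":
        points = embeddings.vectors
    else:
        raise ValueError(f"nodes must be 'terms' or 'all', got {nodes!r}")
    labels, centroids = kmeans(points, k, seed=seed)
    return ClusteringResult(
        labels=labels,
        k=k,
        centroids=centroids,
        silhouette=silhouette_score(points, labels),
        davies_bouldin=davies_bouldin_score(points, labels),
    )


def _config_key(config: WalkConfig) -> tuple:
    return (
        config.dimensions, config.walk_length, config.walks_per_node,
        config.p, config.q, config.context_size, config.negative_samples,
        config.epochs, config.seed,
    )


def select_hyperparameters(
    results: Mapping[WalkConfig, Tuple[float, float]]
    | Iterable[Tuple[WalkConfig, float, float]],
) -> WalkConfig:
    """Pick the best configuration: highest Silhouette, then lowest
    Davies-Bouldin, then a fixed ordering of the config fields, so the
    selection is independent of input order."""
    if isinstance(results, Mapping):
        entries = [(cfg, s, db) for cfg, (s, db) in results.items()]
    else:
        entries = list(results)
    if not entries:
        raise ValueError("no results to select from")
    entries.sort(key=lambda e: (-e[1], e[2], _config_key(e[0])))
    return entries[0][0]


def grid_report(
    results: Iterable[Tuple[WalkConfig, float, float]]
) -> pd.DataFrame:
    """Ranked TSV-ready report of a (partial) grid evaluation."""
    entries = sorted(results, key=lambda e: (-e[1], e[2], _config_key(e[0])))
    rows = []
    for rank, (cfg, s, db) in enumerate(entries, start=1):
        row = {f: getattr(cfg, f) for f in (
            "dimensions", "walk_length", "walks_per_node", "p", "q",
            "context_size", "negative_samples", "epochs", "seed",
        )}
        row.update(silhouette=s, davies_bouldin=db, rank=rank)
        rows.append(row)
    return pd.DataFrame(rows)
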