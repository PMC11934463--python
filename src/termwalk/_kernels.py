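"""Numba kernels for biased second-order walks and skip-gram training.

Both kernels are single-threaded and seed their RNG explicitly, so a fixed
seed gives bit-identical output.  The walk kernel implements the general
second-order rule (return weight 1/p, common-neighbor weight 1, exploration
weight 1/q); adjacency of the candidate to the previous node is decided by
binary search in its sorted CSR neighbor list, so the kernel does not assume
bipartiteness even though on a bipartite graph the weight-1 branch is
unreachable for candidates other than the previous node itself.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NOISE_TABLE_SIZE = 1 << 17


@njit(cache=True)
def _contains(sorted_arr, lo, hi, x):  # pragma: no cover - numba
    while lo < hi:
        mid = (lo + hi) // 2
        v = sorted_arr[mid]
        if v == x:
            return True
        if v < x:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def simulate_walks_kernel(indptr, indices, starts, walk_length, p, q, seed):
    """Run one biased walk of ``walk_length`` steps from each start node.

    Returns an ``(len(starts), walk_length + 1)`` int64 matrix.  The first
    step is uniform over the start's neighbors (no predecessor); later
    steps weight each candidate x by 1/p (x == prev), 1 (x adjacent to
    prev) or 1/q, normalized over the current node's neighbors.
    """
    np.random.seed(seed)
    n_walks = starts.shape[0]
    walks = np.empty((n_walks, walk_length + 1), dtype=np.int64)
    inv_p = 1.0 / p
    inv_q = 1.0 / q
    weights = np.empty(indices.shape[0], dtype=np.float64)
    for w in range(n_walks):
        cur = starts[w]
        walks[w, 0] = cur
        lo = indptr[cur]
        hi = indptr[cur + 1]
        cur = indices[lo + np.random.randint(0, hi - lo)]
        walks[w, 1] = cur
        prev = walks[w, 0]
        for step in range(2, walk_length + 1):
            lo = indptr[cur]
            hi = indptr[cur + 1]
            plo = indptr[prev]
            phi = indptr[prev + 1]
            total = 0.0
            for j in range(lo, hi):
                x = indices[j]
                if x == prev:
                    wgt = inv_p
                elif _contains(indices, plo, phi, x):
                    wgt = 1.0
                else:
                    wgt = inv_q
                total += wgt
                weights[j] = total
            r = np.random.random() * total
            nxt = indices[hi - 1]
            for j in range(lo, hi):
                if r <= weights[j]:
                    nxt = indices[j]
                    break
            walks[w, step] = nxt
            prev = cur
            cur = nxt
    return walks


@njit(cache=True)
def sgns_train_kernel(walks, syn0, syn1, noise_table, context_size,
                      negative_samples, epochs, initial_lr, min_lr, seed):
    """Skip-gram with negative sampling over walk contexts, in place.

    ``syn0`` is the center (output) matrix, ``syn1`` the context matrix.
    One positive update per (center, context) pair within ``context_size``
    on each side, plus ``negative_samples`` negatives drawn from
    ``noise_table``.  The learning rate decays linearly from ``initial_lr``
    to ``min_lr`` over all scheduled center positions.
    """
    np.random.seed(seed)
    n_walks, walk_nodes = walks.shape
    d = syn0.shape[1]
    table_size = noise_table.shape[0]
    grad = np.empty(d, dtype=np.float64)
    total_centers = epochs * n_walks * walk_nodes
    seen = 0
    lr = initial_lr
    for _epoch in range(epochs):
        for w in range(n_walks):
            for pos in range(walk_nodes):
                lr = initial_lr - (initial_lr - min_lr) * (seen / total_centers)
                seen += 1
                center = walks[w, pos]
                left = pos - context_size
                if left < 0:
                    left = 0
                right = pos + context_size
                if right > walk_nodes - 1:
                    right = walk_nodes - 1
                for cpos in range(left, right + 1):
                    if cpos == pos:
                        continue
                    context = walks[w, cpos]
                    for k in range(d):
                        grad[k] = 0.0
                    for s in range(negative_samples + 1):
                        if s == 0:
                            target = context
                            label = 1.0
                        else:
                            target = noise_table[
                                np.random.randint(0, table_size)
                            ]
                            if target == context:
                                continue
                            label = 0.0
                        dot = 0.0
                        for k in range(d):
                            dot += syn0[center, k] * syn1[target, k]
                        if dot > 8.0:
                            sig = 1.0
                        elif dot < -8.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + np.exp(-dot))
                        g = (label - sig) * lr
                        for k in range(d):
                            grad[k] += g * syn1[target, k]
                            syn1[target, k] += g * syn0[center, k]
                    for k in range(d):
                        syn0[center, k] += grad[k]
    return syn0


@njit(cache=True)
def sgns_project_kernel(walks, syn0, host_frozen_rows, noise_table,
                        context_size, negative_samples, epochs,
                        initial_lr, min_lr, seed):
    """Skip-gram updates where rows < ``host_frozen_rows`` are read-only.

    Used to place foreign term nodes in a frozen host space: the host
    vectors serve as fixed context targets (``syn1 := syn0`` semantics),
    and only the appended rows of ``syn0`` receive gradients.
    """
    np.random.seed(seed)
    n_walks, walk_nodes = walks.shape
    d = syn0.shape[1]
    table_size = noise_table.shape[0]
    total_centers = epochs * n_walks * walk_nodes
    seen = 0
    for _epoch in range(epochs):
        for w in range(n_walks):
            for pos in range(walk_nodes):
                lr = initial_lr - (initial_lr - min_lr) * (seen / total_centers)
                seen += 1
                center = walks[w, pos]
                if center < host_frozen_rows:
                    continue
                left = pos - context_size
                if left < 0:
                    left = 0
                right = pos + context_size
                if right > walk_nodes - 1:
                    right = walk_nodes - 1
                for cpos in range(left, right + 1):
                    if cpos == pos:
                        continue
                    context = walks[w, cpos]
                    for s in range(negative_samples + 1):
                        if s == 0:
                            target = context
                            label = 1.0
                        else:
                            target = noise_table[
                                np.random.randint(0, table_size)
                            ]
                            if target == context:
                                continue
                            label = 0.0
                        dot = 0.0
                        for k in range(d):
                            dot += syn0[center, k] * syn0[target, k]
                        if dot > 8.0:
                            sig = 1.0
                        elif dot < -8.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + np.exp(-dot))
                        g = (label - sig) * lr
                        for k in range(d):
                            syn0[center, k] += g * syn0[target, k]
    return syn0
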