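"""Generalized Louvain over a dense (possibly signed) quality matrix.

The multiscale clustering objective is the sum of quality-matrix entries
over same-community pairs.  Standard Louvain implementations optimize graph
modularity only, so the local-move/aggregate loop is written here directly
and jit-compiled; the quality matrix may contain negative entries.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GAIN_EPS = 1e-12


@njit(cache=True)
def _move_nodes(B: np.ndarray, comm: np.ndarray) -> bool:
    m = B.shape[0]
    order = np.arange(m)
    w = np.zeros(m)
    improved = False
    moved = True
    while moved:
        moved = False
        np.random.shuffle(order)
        for oi in range(m):
            u = order[oi]
            for c in range(m):
                w[c] = 0.0
            for v in range(m):
                if v != u:
                    w[comm[v]] += B[u, v]
            cu = comm[u]
            best_c = cu
            best = w[cu]
            for c in range(m):
                if w[c] > best + _GAIN_EPS:
                    best = w[c]
                    best_c = c
            if best_c != cu:
                comm[u] = best_c
                moved = True
                improved = True
    return improved


@njit(cache=True)
def louvain_dense(Q: np.ndarray, seed: int) -> np.ndarray:
    """One Louvain run maximizing sum_{same community} Q[u, v].

    Q must be symmetric.  Returns a community label per node (0-based,
    compact).  Node order within each sweep is shuffled under ``seed``.
    """
    np.random.seed(seed)
    n = Q.shape[0]
    B = Q.copy()
    node2cur = np.arange(n)
    assign = np.arange(n)
    while True:
        m = B.shape[0]
        comm = np.arange(m)
        improved = _move_nodes(B, comm)
        remap = -np.ones(m, np.int64)
        k = 0
        for u in range(m):
            if remap[comm[u]] < 0:
                remap[comm[u]] = k
                k += 1
        for u in range(m):
            comm[u] = remap[comm[u]]
        if not improved or k == m:
            for v in range(n):
                assign[v] = comm[node2cur[v]]
            return assign
        newB = np.zeros((k, k))
        for u in range(m):
            cu = comm[u]
            for v in range(m):
                newB[cu, comm[v]] += B[u, v]
        for v in range(n):
            node2cur[v] = comm[node2cur[v]]
        B = newB
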