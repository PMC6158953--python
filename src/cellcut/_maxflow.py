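"""Edmonds-Karp max-flow kernel on a paired-arc residual representation.

Arcs are stored so that arc ``i ^ 1`` is the residual partner of arc ``i``.
Adjacency is CSR with arcs in increasing arc-index order per tail node, and
the BFS scans nodes/arcs in that fixed order, so the computation is fully
deterministic for a given arc list.  The hot loop is numba-compiled when
numba is importable and falls back to pure Python otherwise.
"""

from __future__ import annotations

import numpy as np

# Residual capacities below this are treated as saturated so float round-off
# cannot produce endless vanishing augmentations.
EPS = 1e-12

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _edmonds_karp(
    n_nodes: int,
    source: int,
    sink: int,
    arc_head: np.ndarray,
    arc_cap: np.ndarray,
    adj_start: np.ndarray,
    adj_arcs: np.ndarray,
) -> float:
    """Run Edmonds-Karp in place on ``arc_cap``; returns the max-flow value."""
    parent_arc = np.empty(n_nodes, dtype=np.int64)
    queue = np.empty(n_nodes, dtype=np.int64)
    total = 0.0
    while True:
        parent_arc[:] = -1
        parent_arc[source] = -2
        queue[0] = source
        head = 0
        tail = 1
        found = False
        while head < tail and not found:
            u = queue[head]
            head += 1
            for k in range(adj_start[u], adj_start[u + 1]):
                a = adj_arcs[k]
                v = arc_head[a]
                if parent_arc[v] == -1 and arc_cap[a] > EPS:
                    parent_arc[v] = a
                    if v == sink:
                        found = True
                        break
                    queue[tail] = v
                    tail += 1
        if not found:
            break
        bottleneck = np.inf
        v = sink
        while v != source:
            a = parent_arc[v]
            if arc_cap[a] < bottleneck:
                bottleneck = arc_cap[a]
            v = arc_head[a ^ 1]
        v = sink
        while v != source:
            a = parent_arc[v]
            arc_cap[a] -= bottleneck
            arc_cap[a ^ 1] += bottleneck
            v = arc_head[a ^ 1]
        total += bottleneck
    return total


@njit(cache=True)
def _source_side(
    n_nodes: int,
    source: int,
    arc_head: np.ndarray,
    arc_cap: np.ndarray,
    adj_start: np.ndarray,
    adj_arcs: np.ndarray,
) -> np.ndarray:
    """Nodes reachable from the source in the residual graph (the min cut)."""
    reach = np.zeros(n_nodes, dtype=np.bool_)
    queue = np.empty(n_nodes, dtype=np.int64)
    reach[source] = True
    queue[0] = source
    head = 0
    tail = 1
    while head < tail:
        u = queue[head]
        head += 1
        for k in range(adj_start[u], adj_start[u + 1]):
            a = adj_arcs[k]
            v = arc_head[a]
            if not reach[v] and arc_cap[a] > EPS:
                reach[v] = True
                queue[tail] = v
                tail += 1
    return reach


def build_adjacency(n_nodes: int, arc_tail: np.ndarray, n_arcs: int):
    """CSR adjacency (arc indices sorted ascending per tail node)."""
    order = np.argsort(arc_tail, kind="stable")
    counts = np.bincount(arc_tail, minlength=n_nodes)
    adj_start = np.zeros(n_nodes + 1, dtype=np.int64)
    np.cumsum(counts, out=adj_start[1:])
    return adj_start, order.astype(np.int64)


def solve(n_nodes, source, sink, arc_tail, arc_head, arc_cap):
    """Max flow + source-side partition; does not mutate ``arc_cap``."""
    residual = np.array(arc_cap, dtype=np.float64)
    adj_start, adj_arcs = build_adjacency(n_nodes, arc_tail, len(arc_head))
    arc_head = np.asarray(arc_head, dtype=np.int64)
    flow = _edmonds_karp(n_nodes, source, sink, arc_head, residual, adj_start, adj_arcs)
    reach = _source_side(n_nodes, source, arc_head, residual, adj_start, adj_arcs)
    return float(flow), np.asarray(reach, dtype=bool)
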