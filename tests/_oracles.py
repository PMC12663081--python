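"""Independent reference computations used only by the tests."""

from __future__ import annotations

import numpy as np


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive simple-path enumeration (no Brandes).

    For every unordered pair, all simple paths are enumerated by DFS, the
    shortest ones kept, and each interior node credited with its fraction of
    those geodesics.  Exponential, so only for small graphs.
    """
    adj = np.asarray(adj)
    n = adj.shape[0]
    neighbors = [np.flatnonzero(adj[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = []
            stack = [(s, (s,))]
            while stack:
                v, path = stack.pop()
                if v == t:
                    paths.append(path)
                    continue
                for w in neighbors[v]:
                    if w not in path:
                        stack.append((int(w), path + (int(w),)))
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            geodesics = [p for p in paths if len(p) == shortest]
            credit = 1.0 / len(geodesics)
            for p in geodesics:
                for v in p[1:-1]:
                    bc[v] += credit
    return bc


def random_graph_fixed_edges(
    n: int, n_edges: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random undirected graph with exactly n_edges edges."""
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.choice(iu.size, size=n_edges, replace=False)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[pick], ju[pick]] = 1
    adj |= adj.T
    return adj
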