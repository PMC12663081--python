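"""Window-wise graph construction and betweenness-centrality ranks.

Each windowed z-matrix is binarized by a proportional threshold that keeps
the strongest 20% of the N(N-1)/2 possible undirected edges (38 of 190 for
N=20), then betweenness centrality is computed on the unweighted graph and
converted to within-window descending ranks (1 = most central node, N =
least; ties receive the average of the spanned ranks).

"Strongest" means largest *signed* z: z-scores above the cut become 1, the
rest 0.  An absolute-value mode is available for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .dfc import DynamicFCSeries
from .errors import ParameterError

__all__ = [
    "BinaryGraphSeries",
    "CentralityTrace",
    "proportional_threshold",
    "betweenness",
    "rank_centrality",
    "threshold_series",
    "centrality_from_graphs",
    "centrality_trace",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class BinaryGraphSeries:
    """W binarized adjacency matrices for one subject at a fixed density."""

    subject_id: str
    adj: np.ndarray  # (W, N, N) uint8, symmetric, zero diagonal
    density: float

    @property
    def n_windows(self) -> int:
        return self.adj.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.adj.shape[1]


@dataclasses.dataclass
class CentralityTrace:
    """Per-window betweenness values and their within-window ranks."""

    subject_id: str
    bc: np.ndarray  # (W, N) raw betweenness, unnormalized
    rank: np.ndarray  # (W, N) descending average-tie ranks in 1..N


def edge_budget(n_nodes: int, density: float) -> int:
    """Number of undirected edges retained at a proportional threshold."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(density * m + 0.5))


def proportional_threshold(
    z_matrix: np.ndarray, density: float = 0.20, absolute: bool = False
) -> np.ndarray:
    """Keep the k = round(density * N(N-1)/2) strongest edges, binarized.

    Boundary ties are broken deterministically by the lexicographically
    smallest (i, j) upper-triangle index pair, so repeated calls and
    platforms agree; a tie at the cut is logged.
    """
    z_matrix = np.asarray(z_matrix, dtype=float)
    n = z_matrix.shape[0]
    if z_matrix.shape != (n, n) or n < 2:
        raise ParameterError("z_matrix must be square with N >= 2")
    if not (0.0 < density < 1.0):
        raise ParameterError("density must lie in (0, 1)")
    k = edge_budget(n, density)
    iu, ju = np.triu_indices(n, k=1)
    weights = z_matrix[iu, ju]
    if absolute:
        weights = np.abs(weights)
    # np.lexsort: last key is primary -> sort by -weight, then i, then j
    order = np.lexsort((ju, iu, -weights))
    chosen = order[:k]
    if k < weights.size and weights[order[k - 1]] == weights[order[k]]:
        n_tied = int(np.sum(weights == weights[order[k - 1]]))
        log.warning(
            "proportional threshold: %d edges tied at the cut weight %.6g; "
            "lexicographic tie-break applied",
            n_tied,
            weights[order[k - 1]],
        )
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[chosen], ju[chosen]] = 1
    adj |= adj.T
    return adj


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness centrality of an undirected binary graph.

    BC(v) = sum over unordered reachable pairs {s, t} (s != v != t) of the
    fraction of shortest s-t paths passing through v.  Disconnected graphs
    are legal: pairs in different components contribute nothing and isolated
    nodes score 0.
    """
    adj = np.asarray(adj)
    g = nx.from_numpy_array((adj != 0).astype(np.uint8))
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(adj.shape[0])], dtype=float)


def rank_centrality(bc_row: np.ndarray) -> np.ndarray:
    """Descending ranks of one window's betweenness values.

    1 = highest centrality, N = lowest; equal values share the average of
    the ranks they span, so every row sums to N(N+1)/2.
    """
    bc_row = np.asarray(bc_row, dtype=float)
    if not np.all(np.isfinite(bc_row)):
        raise ParameterError("betweenness values must be finite")
    return rankdata(-bc_row)


def threshold_series(
    dfc: DynamicFCSeries, density: float = 0.20, absolute: bool = False
) -> BinaryGraphSeries:
    """Binarize every windowed z-matrix of a subject at one density."""
    adj = np.stack(
        [proportional_threshold(zw, density, absolute=absolute) for zw in dfc.z]
    )
    return BinaryGraphSeries(subject_id=dfc.subject_id, adj=adj, density=density)


def centrality_from_graphs(graphs: BinaryGraphSeries) -> CentralityTrace:
    """Betweenness and rank traces over a subject's binarized windows."""
    bc = np.stack([betweenness(a) for a in graphs.adj])
    rank = np.stack([rank_centrality(row) for row in bc])
    return CentralityTrace(subject_id=graphs.subject_id, bc=bc, rank=rank)


def centrality_trace(
    dfc: DynamicFCSeries, density: float = 0.20, absolute: bool = False
) -> CentralityTrace:
    """Convenience: threshold then rank betweenness, window by window."""
    return centrality_from_graphs(threshold_series(dfc, density, absolute=absolute))
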