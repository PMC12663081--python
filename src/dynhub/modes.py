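"""Per-node centrality modes: 1-D k-means under the cityblock metric.

For each node the windowed betweenness ranks of all subjects are concatenated
along time and clustered into k "centrality modes".  Because the metric is
cityblock (Manhattan) and the observations are one-dimensional, the
metric-consistent centroid update is the cluster *median*; the solver below
exploits the 1-D geometry (clusters are contiguous blocks of the sorted data)
so one iteration costs O(k log n) after an initial sort.

The cluster count is chosen per node by maximizing a mixed performance
criterion

    MPFC = (CS * AS * DI) / DB

where CS is the average cluster size n/k, AS the mean silhouette, DI the
Dunn index (minimum inter-cluster distance over maximum intra-cluster
diameter) and DB the Davies-Bouldin index, all under cityblock distance.

The mode with the smallest centroid (mean rank closest to 1, i.e. highest
centrality) is the high-centrality mode (HCM); a subject's HCM occupancy is
the number of windows spent in it.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .errors import ParameterError
from .topology import CentralityTrace

__all__ = [
    "ModeModel",
    "mean_silhouette",
    "mpfc",
    "fit_modes",
    "hcm_occupancy",
    "fit_cohort_modes",
]

log = logging.getLogger(__name__)

DEFAULT_K_GRID = (2, 3, 4, 5, 6)


class EmptyClusterError(ParameterError):
    """A candidate clustering left some cluster empty; MPFC is undefined."""


@dataclasses.dataclass
class ModeModel:
    """Fitted centrality modes for one node.

    Modes are relabeled by ascending centroid, so mode 0 is always the
    high-centrality mode (smallest mean rank).
    """

    node: int
    k: int
    centroids: np.ndarray  # (k,) ascending
    labels: list[np.ndarray]  # per subject, length W_subject, values 0..k-1
    hcm_id: int
    mpfc_by_k: dict[int, float]


# ---------------------------------------------------------------------------
# 1-D cityblock machinery (sorted values + prefix sums)
# ---------------------------------------------------------------------------

def _total_abs_dist(x: np.ndarray, sorted_vals: np.ndarray, prefix: np.ndarray):
    """Sum of |x - v| over v in sorted_vals, vectorized over x."""
    pos = np.searchsorted(sorted_vals, x)
    m = sorted_vals.size
    left = x * pos - prefix[pos]
    right = (prefix[m] - prefix[pos]) - x * (m - pos)
    return left + right


def _block_cost(xs: np.ndarray, prefix: np.ndarray, lo: int, hi: int, c: float):
    """Cityblock cost of assigning sorted xs[lo:hi] to centroid c."""
    pos = np.searchsorted(xs[lo:hi], c) + lo
    left = c * (pos - lo) - (prefix[pos] - prefix[lo])
    right = (prefix[hi] - prefix[pos]) - c * (hi - pos)
    return left + right


def _assign_blocks(xs: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Block edges of the nearest-centroid partition of sorted data.

    Centroids must be ascending; points equal to a midpoint go to the lower
    cluster (deterministic).
    """
    bounds = 0.5 * (centroids[:-1] + centroids[1:])
    edges = np.searchsorted(xs, bounds, side="right")
    return np.concatenate(([0], edges, [xs.size]))


def _kmedians_sorted(
    xs: np.ndarray,
    prefix: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_restarts: int = 20,
    max_iter: int = 300,
) -> tuple[np.ndarray, float, bool]:
    """Seeded k-medians on sorted 1-D data; returns (centroids, cost, converged)."""
    n = xs.size
    best_centroids, best_cost, best_conv = None, math.inf, True
    for _ in range(n_restarts):
        # k-means++-style seeding with cityblock distances
        centroids = np.empty(k)
        centroids[0] = xs[rng.integers(n)]
        dist = np.abs(xs - centroids[0])
        for j in range(1, k):
            total = dist.sum()
            if total <= 0:
                centroids[j:] = xs[0]
                break
            r = rng.random() * total
            idx = int(np.searchsorted(np.cumsum(dist), r))
            centroids[j] = xs[min(idx, n - 1)]
            np.minimum(dist, np.abs(xs - centroids[j]), out=dist)
        centroids.sort()

        converged = False
        for _it in range(max_iter):
            edges = _assign_blocks(xs, centroids)
            sizes = np.diff(edges)
            if np.any(sizes == 0):
                # relocate empty centroids to the current worst-served point
                d_near = np.min(np.abs(xs[:, None] - centroids[None, :]), axis=1)
                for j in np.flatnonzero(sizes == 0):
                    far = int(np.argmax(d_near))
                    centroids[j] = xs[far]
                    d_near[far] = -1.0
                centroids.sort()
                continue
            new = np.empty(k)
            for j in range(k):
                lo, hi = edges[j], edges[j + 1]
                sz = hi - lo
                new[j] = 0.5 * (xs[lo + (sz - 1) // 2] + xs[lo + sz // 2])
            if np.array_equal(new, centroids):
                converged = True
                break
            centroids = new
        edges = _assign_blocks(xs, centroids)
        cost = sum(
            _block_cost(xs, prefix, edges[j], edges[j + 1], centroids[j])
            for j in range(k)
        )
        if cost < best_cost - 1e-12 or (
            best_centroids is None
        ):
            best_centroids, best_cost, best_conv = centroids.copy(), cost, converged
    if not best_conv:
        log.warning("k-medians did not converge within max_iter; best iterate used")
    return best_centroids, best_cost, best_conv


# ---------------------------------------------------------------------------
# MPFC criterion
# ---------------------------------------------------------------------------

def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette s(i) = (b-a)/max(a,b) under cityblock distance.

    a(i): mean distance to the other members of i's cluster (0 for a
    singleton); b(i): smallest mean distance to another cluster.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    k = int(labels.max()) + 1
    n = points.size
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):
        raise EmptyClusterError("empty cluster")
    clusters = [np.sort(points[labels == c]) for c in range(k)]
    prefixes = [np.concatenate(([0.0], np.cumsum(c))) for c in clusters]
    totals = np.column_stack(
        [_total_abs_dist(points, clusters[c], prefixes[c]) for c in range(k)]
    )
    own = sizes[labels]
    a = np.where(own > 1, totals[np.arange(n), labels] / np.maximum(own - 1, 1), 0.0)
    mean_other = totals / sizes[None, :]
    mean_other[np.arange(n), labels] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    sil = np.where(
        (denom > 0) & (own > 1), (b - a) / np.where(denom > 0, denom, 1.0), 0.0
    )
    return float(sil.mean())


def mpfc(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Mixed performance criterion (CS * AS * DI) / DB for a 1-D clustering.

    Returns ``-inf`` when two centroids coincide (Davies-Bouldin denominator
    is zero) and ``+inf`` for a perfectly separated clustering in which every
    cluster has zero diameter but clusters are apart (Dunn index diverges).

    Raises
    ------
    EmptyClusterError
        If some label in 0..k-1 has no member; the criterion is undefined
        for that clustering.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    centroids = np.asarray(centroids, dtype=float)
    k = centroids.size
    n = points.size
    if k < 2:
        raise ParameterError("MPFC needs k >= 2")
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):
        raise EmptyClusterError(f"empty cluster among k={k}")

    clusters = [np.sort(points[labels == c]) for c in range(k)]
    prefixes = [np.concatenate(([0.0], np.cumsum(c))) for c in clusters]
    avg_sil = mean_silhouette(points, labels)

    # Dunn index: min inter-cluster gap over max intra-cluster diameter
    order = np.argsort(points, kind="stable")
    sorted_labels = labels[order]
    sorted_points = points[order]
    boundary = sorted_labels[1:] != sorted_labels[:-1]
    gaps = np.abs(np.diff(sorted_points))[boundary]
    min_inter = float(gaps.min()) if gaps.size else 0.0
    max_diam = max(float(c[-1] - c[0]) for c in clusters)

    # Davies-Bouldin with cityblock scatter about the given centroids
    scatter = np.array(
        [
            _total_abs_dist(np.array([centroids[c]]), clusters[c], prefixes[c])[0]
            / sizes[c]
            for c in range(k)
        ]
    )
    sep = np.abs(centroids[:, None] - centroids[None, :])
    if np.any(sep[~np.eye(k, dtype=bool)] == 0.0):
        return -math.inf
    with np.errstate(divide="ignore"):
        ratio = (scatter[:, None] + scatter[None, :]) / np.where(sep > 0, sep, np.inf)
    np.fill_diagonal(ratio, -math.inf)
    db = float(ratio.max(axis=1).mean())

    cs = n / k
    if max_diam == 0.0:
        return math.inf if min_inter > 0 else -math.inf
    dunn = min_inter / max_diam
    if db == 0.0:
        return -math.inf
    return (cs * avg_sil * dunn) / db


# ---------------------------------------------------------------------------
# Model selection and occupancy
# ---------------------------------------------------------------------------

def fit_modes(
    rank_traces: list[np.ndarray],
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    seed: int = 0,
    node: int = 0,
    n_restarts: int = 20,
) -> ModeModel:
    """Cluster one node's cohort-concatenated windowed ranks into modes.

    Parameters
    ----------
    rank_traces : list of 1-D arrays
        Per-subject sequences of the node's windowed rank-betweenness values,
        in window order.
    k_grid : candidate cluster counts (each >= 2)
    seed : int
        Drives k-means++ restarts; fixed seed + fixed inputs reproduce the
        model exactly.
    node : int
        Node index recorded in the model (also salts the seed so different
        nodes explore different restarts).
    """
    if any(k < 2 for k in k_grid):
        raise ParameterError("k_grid entries must be >= 2")
    lengths = [len(t) for t in rank_traces]
    points = np.concatenate([np.asarray(t, dtype=float) for t in rank_traces])
    n = points.size
    if n <= max(k_grid):
        raise ParameterError("need more observations than the largest candidate k")

    order = np.argsort(points, kind="stable")
    xs = points[order]
    prefix = np.concatenate(([0.0], np.cumsum(xs)))
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(node)])

    scores: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in sorted(k_grid):
        centroids, _cost, _conv = _kmedians_sorted(
            xs, prefix, k, rng, n_restarts=n_restarts
        )
        edges = _assign_blocks(xs, centroids)
        labels_sorted = np.repeat(np.arange(k), np.diff(edges))
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
        try:
            scores[k] = mpfc(points, labels, centroids)
        except EmptyClusterError:
            log.info("node %d: k=%d leaves an empty cluster; excluded", node, k)
            scores[k] = -math.inf
        fits[k] = (centroids, labels)

    finite_best = max(scores.values())
    if not math.isfinite(finite_best) and finite_best < 0:
        log.warning(
            "node %d: no candidate k achieved a defined MPFC (low separation); "
            "falling back to the smallest k",
            node,
        )
    # argmax with smallest-k tie-break (also covers several +inf scores)
    best_k = min(k for k in scores if scores[k] == finite_best)
    centroids, labels = fits[best_k]

    # relabel modes by ascending centroid; mode 0 = high-centrality mode
    perm = np.argsort(centroids, kind="stable")
    inverse = np.empty(best_k, dtype=int)
    inverse[perm] = np.arange(best_k)
    labels = inverse[labels]
    centroids = centroids[perm]

    per_subject = []
    start = 0
    for w in lengths:
        per_subject.append(labels[start : start + w].copy())
        start += w
    return ModeModel(
        node=node,
        k=best_k,
        centroids=centroids,
        labels=per_subject,
        hcm_id=0,
        mpfc_by_k=scores,
    )


def hcm_occupancy(model: ModeModel) -> np.ndarray:
    """Number of windows each subject spends in the high-centrality mode."""
    return np.array(
        [int(np.sum(lbl == model.hcm_id)) for lbl in model.labels], dtype=int
    )


def fit_cohort_modes(
    traces: list[CentralityTrace],
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    seed: int = 0,
    n_restarts: int = 20,
    node_labels: list[str] | None = None,
) -> tuple[list[ModeModel], pd.DataFrame]:
    """Fit a ModeModel per node and tabulate HCM occupancy (subject x node)."""
    n_nodes = traces[0].rank.shape[1]
    subject_ids = [t.subject_id for t in traces]
    models = []
    occupancy = np.zeros((len(traces), n_nodes), dtype=int)
    for node in range(n_nodes):
        model = fit_modes(
            [t.rank[:, node] for t in traces],
            k_grid=k_grid,
            seed=seed,
            node=node,
            n_restarts=n_restarts,
        )
        models.append(model)
        occupancy[:, node] = hcm_occupancy(model)
    columns = node_labels if node_labels is not None else list(range(n_nodes))
    table = pd.DataFrame(occupancy, index=subject_ids, columns=columns)
    table.index.name = "subject_id"
    return models, table
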