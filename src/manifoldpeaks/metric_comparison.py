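"""Comparing distance measures: neighborhood overlap, information
imbalance, and greedy feature selection.

Two representations (metrics) of the same N points can be compared
purely through distance ranks.  The neighborhood overlap

    chi(a, b) = (1/N) sum_i |kNN_a(i) intersect kNN_b(i)| / k

is the average fraction of shared k-nearest neighbors: 1 for equivalent
representations, 0 for completely unrelated ones, and symmetric by
construction.  The information imbalance

    Delta(a -> b) = (2/N^2) sum_i r^b(i, nn_a(i))

is (up to the 2/N scaling) the mean rank, under metric b, of each
point's nearest neighbor under metric a: near 0 when a predicts b, near
1 when the two metrics are independent — and asymmetric in general,
which is what lets it detect that one representation is *more
informative* than another.  Greedy forward selection uses it to pick,
one at a time, the features whose subspace-distance best predicts a
target metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .neighbors import NeighborGraph, PointCloud, build_neighbor_graph

DEFAULT_K_OVERLAP = 30

__all__ = [
    "MetricPair",
    "ImbalanceResult",
    "neighborhood_overlap",
    "information_imbalance",
    "greedy_feature_selection",
    "conditional_ranks",
]


@dataclass(frozen=True)
class MetricPair:
    """Two neighbor graphs over the same point set, plus the k for chi."""

    graph_a: NeighborGraph
    graph_b: NeighborGraph
    k_overlap: int = DEFAULT_K_OVERLAP

    def __post_init__(self):
        if self.graph_a.n_points != self.graph_b.n_points:
            raise ValueError("the two metrics must cover the same points")

    @property
    def n_points(self) -> int:
        return self.graph_a.n_points


@dataclass(frozen=True)
class ImbalanceResult:
    """Information imbalance in both directions (each in [2/N, 2))."""

    delta_ab: float
    delta_ba: float


def neighborhood_overlap(pair: MetricPair, k: int | None = None) -> float:
    """Average fraction of shared k-nearest neighbors between a and b."""
    k = pair.k_overlap if k is None else int(k)
    ga, gb = pair.graph_a, pair.graph_b
    if k < 1 or k > ga.maxk or k > gb.maxk:
        raise ValueError(f"k_overlap={k} exceeds the available neighbors")
    shared = 0
    for i in range(pair.n_points):
        shared += len(np.intersect1d(ga.nn_index[i, :k], gb.nn_index[i, :k]))
    return shared / (pair.n_points * k)


def conditional_ranks(graph: NeighborGraph, targets: np.ndarray) -> np.ndarray:
    """Exact rank, under this graph's metric, of targets[i] w.r.t. point i.

    Rank 1 = nearest neighbor.  Ranks are computed from full distance
    rows (ties broken by ascending id, as everywhere), so they are exact
    even when the target falls beyond the maxk truncation.
    """
    n = graph.n_points
    ranks = np.empty(n, dtype=np.int64)
    ids = np.arange(n)
    for i in range(n):
        j = targets[i]
        row = graph.distance_row(i)
        dj = row[j]
        closer = (row < dj) | ((row == dj) & (ids < j))
        closer[i] = False
        ranks[i] = int(np.count_nonzero(closer)) + 1
    return ranks


def information_imbalance(pair: MetricPair, subsample: int | None = None,
                          seed: int | None = None) -> ImbalanceResult:
    """Information imbalance Delta(a->b) and Delta(b->a).

    Conditional ranks are exact (full search, not maxk-truncated).  For
    very large N a seeded row subsample can be requested; the sum is
    then rescaled to the full-N convention.
    """
    ga, gb = pair.graph_a, pair.graph_b
    n = pair.n_points
    rows = np.arange(n)
    if subsample is not None and subsample < n:
        if seed is None:
            raise ValueError("subsampled imbalance requires a seed")
        rows = np.random.default_rng(seed).choice(n, size=subsample, replace=False)

    nn_a = ga.nn_index[:, 0]
    nn_b = gb.nn_index[:, 0]
    r_b = conditional_ranks(gb, nn_a)[rows]
    r_a = conditional_ranks(ga, nn_b)[rows]
    scale = 2.0 / (n * len(rows))
    return ImbalanceResult(float(scale * r_b.sum()), float(scale * r_a.sum()))


def _full_rank_matrix(graph: NeighborGraph) -> np.ndarray:
    """N x N matrix of exact distance ranks (0 on the diagonal)."""
    n = graph.n_points
    ids = np.arange(n)
    ranks = np.empty((n, n), dtype=np.int32)
    for i in range(n):
        row = graph.distance_row(i).copy()
        row[i] = -np.inf  # self first, becomes rank 0
        order = np.lexsort((ids, row))
        ranks[i, order] = ids
    return ranks


def greedy_feature_selection(
    cloud: PointCloud,
    target_graph: NeighborGraph,
    n_select: int,
    standardize: bool = False,
) -> tuple[list, np.ndarray]:
    """Forward feature selection by information imbalance to a target.

    At each step the feature whose addition minimizes
    Delta(subset -> target) joins the subset (Euclidean distance over
    the selected columns).  Returns the ordered selected features and
    the Delta trace, reported as measured: it typically decreases to a
    plateau but is not guaranteed monotone.
    """
    if not target_graph.has_full_distances:
        raise ValueError("target graph must carry coordinates or full distances")
    x = np.asarray(cloud.coords, dtype=float)
    n, d = x.shape
    if not 1 <= n_select <= d:
        raise ValueError("need 1 <= n_select <= number of features")
    spread = x.std(axis=0)
    usable = spread > 0
    if not usable.all():
        warnings.warn(f"skipping constant feature(s) {np.flatnonzero(~usable).tolist()}")
    if standardize:
        x = np.where(usable, (x - x.mean(axis=0)) / np.where(usable, spread, 1.0), x)

    rank_t = _full_rank_matrix(target_graph)
    ids = np.arange(n)

    def delta_for(cols: list) -> float:
        sub = x[:, cols]
        total = 0
        for i in range(n):
            dvals = np.linalg.norm(sub - sub[i], axis=1)
            dvals[i] = np.inf
            j = np.lexsort((ids, dvals))[0]
            total += rank_t[i, j]
        return 2.0 * total / n**2

    selected: list = []
    trace = []
    for _ in range(n_select):
        best_f, best_delta = None, np.inf
        for fidx in range(d):
            if fidx in selected or not usable[fidx]:
                continue
            val = delta_for(selected + [fidx])
            if val < best_delta - 1e-15:
                best_f, best_delta = fidx, val
        if best_f is None:
            break
        selected.append(best_f)
        trace.append(best_delta)
    return selected, np.asarray(trace)
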