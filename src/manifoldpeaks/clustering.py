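"""Density-peak clustering: decision graph, ADP merging, dendrogram.

Clusters are identified with the peaks of the estimated density.  The
classic density-peak (DP) route computes, for every point, the distance
delta_i to its nearest point of higher density; cluster centers are the
points where both the density and delta are large (chosen by the user),
and every other point inherits the cluster of its nearest
higher-density neighbor.

The automatic (ADP) route starts from *all* local density maxima and
merges statistically indistinguishable ones: a peak c survives against
a neighboring saddle cc' only if

    ln rho_c - ln rho_cc' > Z (sigma_c + sigma_cc'),

i.e. the peak rises above the saddle by more than Z times the summed
errors on the two log-densities.  Merging is iterated to a fixed point,
so the final number of clusters decreases as the significance threshold
Z grows (typical values 1 to 5).

Ties in density are broken by point id (lower id counts as higher), so
all results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix

from .density import DensityEstimate
from .neighbors import NeighborGraph

DEFAULT_Z = 1.65

__all__ = [
    "DecisionGraph",
    "ClusterResult",
    "DendrogramSummary",
    "decision_graph",
    "dp_cluster",
    "adp_cluster",
    "find_saddles",
    "dendrogram_summary",
]


@dataclass(frozen=True)
class DecisionGraph:
    """Per-point delta_i (distance to the nearest higher-density point)
    and the id of that point (-1 for the global density maximum, whose
    delta is set to its largest distance to any point)."""

    delta: np.ndarray
    nneigh_higher: np.ndarray
    density: DensityEstimate

    def __post_init__(self):
        if np.any(self.delta <= 0):
            raise ValueError("delta must be positive")


@dataclass(frozen=True)
class ClusterResult:
    """Labels (0..C-1), peak point ids, and the peak/saddle matrices.

    saddle_logden[c, c'] is the log-density of the highest border point
    between clusters c and c' (NaN where the clusters share no border),
    saddle_err its error; peak_logden/peak_err are per-cluster peak
    values; population counts points per cluster.
    """

    labels: np.ndarray
    centers: np.ndarray
    saddle_logden: np.ndarray
    saddle_err: np.ndarray
    peak_logden: np.ndarray
    peak_err: np.ndarray
    population: np.ndarray
    z_threshold: float | None = None

    def __post_init__(self):
        if self.population.sum() != len(self.labels):
            raise ValueError("populations must sum to N")
        for c, center in enumerate(self.centers):
            if self.labels[center] != c:
                raise ValueError("each center must carry its own cluster label")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class DendrogramSummary:
    """Plain-data dendrogram: peaks and saddles by log-density, with
    each cluster centered in an x-span proportional to its population."""

    peaks: list
    saddles: list


def _higher(f: np.ndarray, j: np.ndarray, i) -> np.ndarray:
    """True where point j ranks above point i in the density order
    (greater F, or equal F and lower id)."""
    return (f[j] > f[i]) | ((f[j] == f[i]) & (j < i))


def _density_order(f: np.ndarray) -> np.ndarray:
    """Point ids from highest to lowest density (ties: lower id first)."""
    return np.lexsort((np.arange(len(f)), -f))


def decision_graph(graph: NeighborGraph, density: DensityEstimate) -> DecisionGraph:
    """delta_i = min distance to any higher-density point.

    The search runs first inside each point's maxk neighborhood; points
    whose neighborhood contains no higher-density point fall back to an
    exact global search (never a truncated guess — a too-small maxk must
    not fabricate spurious peaks).  The global maximum gets
    delta = max_j d_ij by convention.
    """
    f = density.log_den
    n = graph.n_points
    if np.all(f == f[0]):
        raise ValueError("degenerate density: all values equal")
    ids = np.arange(n)

    nn = graph.nn_index
    higher = _higher(f, nn, ids[:, None])
    has = higher.any(axis=1)
    first = np.argmax(higher, axis=1)

    delta = np.empty(n)
    nneigh = np.full(n, -1, dtype=np.int64)
    delta[has] = graph.nn_dist[ids[has], first[has]]
    nneigh[has] = nn[ids[has], first[has]]

    top = _density_order(f)[0]
    for i in ids[~has]:
        row = graph.distance_row(i)
        if i == top:
            delta[i] = row.max()
            continue
        mask = _higher(f, ids, i)
        cand_d = np.where(mask, row, np.inf)
        j = np.lexsort((ids, cand_d))[0]
        delta[i] = cand_d[j]
        nneigh[i] = j
    if delta[top] <= 0:
        raise ValueError("degenerate dataset: zero maximal distance")
    return DecisionGraph(delta, nneigh, density)


def _assign(dg: DecisionGraph, centers: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Descending-density assignment: non-centers inherit the label of
    their nearest higher-density neighbor."""
    f = dg.density.log_den
    n = len(f)
    labels = np.full(n, -1, dtype=np.int64)
    labels[centers] = np.arange(len(centers))
    for i in _density_order(f):
        if labels[i] >= 0:
            continue
        j = dg.nneigh_higher[i]
        if j < 0:  # global max not chosen as a center: nearest center wins
            row = graph.distance_row(i)
            j = centers[np.argmin(row[centers])]
        labels[i] = labels[j]
    return labels


def _order_centers(centers: np.ndarray, f: np.ndarray) -> np.ndarray:
    return centers[np.lexsort((centers, -f[centers]))]


def dp_cluster(
    dg: DecisionGraph,
    graph: NeighborGraph,
    centers=None,
    rho_min: float | None = None,
    delta_min: float | None = None,
) -> ClusterResult:
    """Classic DP clustering with user-chosen centers.

    Centers are either explicit point ids or the points with
    log-density > rho_min and delta > delta_min; clusters are numbered
    by descending peak density.
    """
    f = dg.density.log_den
    if centers is None:
        if rho_min is None or delta_min is None:
            raise ValueError("give explicit centers or both rho_min and delta_min")
        centers = np.flatnonzero((f > rho_min) & (dg.delta > delta_min))
    centers = np.asarray(centers, dtype=np.int64)
    if len(centers) == 0:
        raise ValueError("empty center set")
    if len(np.unique(centers)) != len(centers):
        raise ValueError("duplicate center ids")
    centers = _order_centers(centers, f)
    labels = _assign(dg, centers, graph)
    sl, se = find_saddles(graph, dg.density, labels, centers)
    pop = np.bincount(labels, minlength=len(centers))
    return ClusterResult(
        labels, centers, sl, se, f[centers], dg.density.err[centers], pop
    )


def _mutual_pairs(graph: NeighborGraph, k_hat: np.ndarray):
    """All ordered point pairs (i, j) that are mutual adapted-scale
    neighbors: j within the first k_hat_i neighbors of i and vice versa."""
    n, maxk = graph.nn_index.shape
    cols = np.arange(maxk)
    inside = cols[None, :] < k_hat[:, None]
    rows = np.repeat(np.arange(n), k_hat)
    js = graph.nn_index[inside]
    a = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, js)), shape=(n, n))
    mutual = a.multiply(a.T).tocoo()
    return mutual.row, mutual.col


def find_saddles(
    graph: NeighborGraph,
    density: DensityEstimate,
    labels: np.ndarray,
    centers: np.ndarray,
):
    """Saddle log-density between every cluster pair.

    A point i of cluster c is a border point toward c' when it has a
    mutual adapted-scale neighbor j in c'.  The saddle value rho_cc' is
    the highest log-density among the border points of the pair (either
    side, peaks excluded) and sigma_cc' is that point's error.  Pairs
    with no border points get NaN (no saddle: fully separated).
    """
    f = density.log_den
    c = len(centers)
    pi, pj = _mutual_pairs(graph, density.k_hat)
    cross = labels[pi] != labels[pj]
    is_center = np.zeros(len(labels), dtype=bool)
    is_center[centers] = True
    cand = cross & ~is_center[pi]  # i side of each cross pair
    pi, pj = pi[cand], pj[cand]

    sl = np.full((c, c), np.nan)
    se = np.full((c, c), np.nan)
    if len(pi) == 0:
        return sl, se
    a = np.minimum(labels[pi], labels[pj])
    b = np.maximum(labels[pi], labels[pj])
    flat = a * c + b
    best = np.full(c * c, -np.inf)
    np.maximum.at(best, flat, f[pi])
    # deterministic attaining point: lowest id among maxima of the pair
    hit = f[pi] == best[flat]
    chosen = np.full(c * c, len(labels), dtype=np.int64)
    np.minimum.at(chosen, flat[hit], pi[hit])
    pairs = np.flatnonzero(np.isfinite(best))
    for p in pairs:
        i, j = divmod(p, c)
        point = chosen[p]
        sl[i, j] = sl[j, i] = best[p]
        se[i, j] = se[j, i] = density.err[point]
    return sl, se


def _local_maxima(graph: NeighborGraph, density: DensityEstimate) -> np.ndarray:
    """Points denser than every neighbor within their adapted neighborhood."""
    f = density.log_den
    n, maxk = graph.nn_index.shape
    cols = np.arange(maxk)
    inside = cols[None, :] < density.k_hat[:, None]
    nn = graph.nn_index
    neigh_higher = _higher(f, nn, np.arange(n)[:, None]) & inside
    return np.flatnonzero(~neigh_higher.any(axis=1))


def adp_cluster(
    graph: NeighborGraph, density: DensityEstimate, z: float = DEFAULT_Z
) -> ClusterResult:
    """Automatic density-peak clustering with significance-based merging.

    All local maxima of the density (within each point's adapted
    neighborhood) start as peaks; points are assigned as in DP
    clustering; saddles between clusters are located; then, as long as
    some lower peak fails the significance test
    F_c - F_cc' <= Z (sigma_c + sigma_cc'), the failing pair with the
    highest saddle density is merged (the lower peak is absorbed into
    the higher one) and the saddles are recomputed.  The loop stops when
    every surviving peak is significant against all its saddles.
    """
    if z < 0:
        raise ValueError("Z must be nonnegative")
    f = density.log_den
    err = density.err
    peaks = _local_maxima(graph, density)
    if len(peaks) == 0:
        raise ValueError("no density maxima (check maxk/density)")
    dg = decision_graph(graph, density)
    centers = _order_centers(peaks, f)
    labels = _assign(dg, centers, graph)

    while True:
        sl, se = find_saddles(graph, density, labels, centers)
        c = len(centers)
        peak_f = f[centers]
        peak_e = err[centers]
        lower = np.minimum.outer(peak_f, peak_f)
        lower_e = np.where(
            peak_f[:, None] <= peak_f[None, :], peak_e[:, None], peak_e[None, :]
        )
        with np.errstate(invalid="ignore"):
            fails = (lower - sl) <= z * (lower_e + se)
        fails &= np.isfinite(sl)
        np.fill_diagonal(fails, False)
        if not fails.any() or c == 1:
            break
        # merge the failing pair with the highest saddle first
        cand = np.where(fails, sl, -np.inf)
        p = int(np.argmax(cand))
        ca, cb = divmod(p, c)
        # absorb the lower peak into the higher one
        drop = cb if peak_f[ca] >= peak_f[cb] else ca
        centers = np.delete(centers, drop)
        # re-assign from the surviving peaks: the running state is always
        # exactly a DP clustering with the current center set
        labels = _assign(dg, centers, graph)

    centers = _order_centers(centers, f)
    labels = _assign(dg, centers, graph)
    sl, se = find_saddles(graph, density, labels, centers)
    pop = np.bincount(labels, minlength=len(centers))
    return ClusterResult(
        labels, centers, sl, se, f[centers], err[centers], pop, z_threshold=z
    )


def dendrogram_summary(result: ClusterResult) -> DendrogramSummary:
    """Peaks and saddles as plottable plain data.

    y values are log-densities; x places cluster c in the middle of a
    span of width proportional to its population, saddles at the
    midpoint of the two peak positions.  No rendering is done here.
    """
    pop = result.population.astype(float)
    right = np.cumsum(pop)
    x = right - pop / 2.0
    peaks = [
        {
            "id": int(result.centers[c]),
            "cluster": int(c),
            "logden": float(result.peak_logden[c]),
            "population": int(result.population[c]),
            "x": float(x[c]),
        }
        for c in range(result.n_clusters)
    ]
    saddles = []
    for a in range(result.n_clusters):
        for b in range(a + 1, result.n_clusters):
            if np.isfinite(result.saddle_logden[a, b]):
                saddles.append(
                    {
                        "c1": int(a),
                        "c2": int(b),
                        "logden": float(result.saddle_logden[a, b]),
                        "x": float(0.5 * (x[a] + x[b])),
                    }
                )
    return DendrogramSummary(peaks, saddles)
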