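"""Truncated nearest-neighbor graphs and rank structures.

Everything downstream (intrinsic dimension, density, clustering, metric
comparison) operates on per-point neighbor lists truncated at ``maxk``
rather than on full N x N distance matrices, so memory and time stay
close to linear in N.  Graphs can be built either from a coordinate
matrix (Euclidean metric) or directly from user-supplied distances, in
which case the metric is whatever the user computed.

Determinism: distance ties are always broken by ascending point id, so
identical inputs produce identical graphs with no seed involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

DEFAULT_MAXK = 100

__all__ = [
    "PointCloud",
    "NeighborGraph",
    "RankMatrix",
    "build_neighbor_graph",
    "from_distances",
    "remove_duplicates",
    "rank_matrix",
    "read_coordinates",
    "read_distances",
    "write_graph_tsv",
]


@dataclass(frozen=True)
class PointCloud:
    """A set of N points in a D-dimensional feature space.

    Coordinates are arbitrary real features; units are whatever the user
    measured.  Point ids are the stable row indices 0..N-1 and survive
    through every downstream result.
    """

    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        if coords.ndim != 2:
            raise ValueError("coords must be an N x D matrix")
        if coords.shape[0] < 2:
            raise ValueError("need at least 2 points")
        if coords.shape[1] < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def n_features(self) -> int:
        return self.coords.shape[1]

    @property
    def point_ids(self) -> np.ndarray:
        return np.arange(self.n_points)


@dataclass
class NeighborGraph:
    """Per-point neighbor lists truncated at ``maxk``, sorted by distance.

    ``nn_index[i]`` holds the ids of the maxk nearest neighbors of point i
    (self excluded), ``nn_dist[i]`` the matching distances in ascending
    order.  ``coords`` and/or ``full_dist`` are kept when available so that
    the few operations that need distances beyond maxk (exact delta
    fallback, exact conditional ranks) can compute them.
    """

    nn_index: np.ndarray
    nn_dist: np.ndarray
    metric_name: str = "euclidean"
    coords: np.ndarray | None = None
    full_dist: np.ndarray | None = None

    def __post_init__(self):
        self.nn_index = np.asarray(self.nn_index, dtype=np.int64)
        self.nn_dist = np.asarray(self.nn_dist, dtype=float)
        if self.nn_index.shape != self.nn_dist.shape or self.nn_index.ndim != 2:
            raise ValueError("nn_index and nn_dist must be matching N x maxk matrices")
        if np.any(self.nn_dist < 0):
            raise ValueError("negative neighbor distance")
        if np.any(np.diff(self.nn_dist, axis=1) < 0):
            raise ValueError("neighbor distances must be row-sorted ascending")

    @property
    def n_points(self) -> int:
        return self.nn_index.shape[0]

    @property
    def maxk(self) -> int:
        return self.nn_index.shape[1]

    def distance_row(self, i: int) -> np.ndarray:
        """Exact distances from point i to every point (d[i]=0).

        Needs coordinates or a stored full matrix; used only by the
        operations that must look beyond the maxk truncation.
        """
        if self.full_dist is not None:
            return self.full_dist[i]
        if self.coords is not None:
            return np.linalg.norm(self.coords - self.coords[i], axis=1)
        raise ValueError(
            "distances beyond maxk requested, but the graph holds neither "
            "coordinates nor a full distance matrix"
        )

    @property
    def has_full_distances(self) -> bool:
        return self.full_dist is not None or self.coords is not None


@dataclass(frozen=True)
class RankMatrix:
    """ranks[i][m] = distance rank of the m-th listed neighbor of i (1 = nearest)."""

    ranks: np.ndarray


def _resolve_maxk(maxk: int | None, n: int) -> int:
    if maxk is None:
        return min(DEFAULT_MAXK, n - 1)
    maxk = int(maxk)
    if maxk < 1:
        raise ValueError("maxk must be >= 1")
    if maxk >= n:
        raise ValueError(f"maxk too large: maxk={maxk} with N={n} (need maxk <= N-1)")
    return maxk


def _tie_sorted_rows(idx: np.ndarray, dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Re-sort each neighbor row by (distance, id): deterministic tie-break."""
    # lexsort with last key primary: distances first, ids break ties
    order = np.lexsort((idx, dist), axis=1)
    rows = np.arange(idx.shape[0])[:, None]
    return idx[rows, order], dist[rows, order]


def build_neighbor_graph(
    cloud: PointCloud | np.ndarray,
    maxk: int | None = None,
    metric: str = "euclidean",
) -> NeighborGraph:
    """Build the truncated neighbor graph from coordinates.

    Identical in content to sorting the full N x N Euclidean distance
    matrix row by row and keeping the first maxk columns, but computed
    with a kd-tree for D <= 20 and chunk-wise brute force above (tree
    structures lose their edge in high dimension).  Both paths return the
    same graph because rows are re-sorted with the (distance, id) key.
    """
    if not isinstance(cloud, PointCloud):
        cloud = PointCloud(cloud)
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported for coordinates")
    n = cloud.n_points
    maxk = _resolve_maxk(maxk, n)

    algo = "kd_tree" if cloud.n_features <= 20 else "brute"
    # one spare neighbor beyond maxk: lets us detect distance ties that
    # straddle the truncation boundary (the tree breaks ties arbitrarily)
    kq = min(n, maxk + 2)
    nn = NearestNeighbors(n_neighbors=kq, algorithm=algo)
    nn.fit(cloud.coords)
    dist, idx = nn.kneighbors(cloud.coords)
    idx, dist = _tie_sorted_rows(idx.astype(np.int64), dist)

    # Drop the self entry from each row (present somewhere among the ties
    # at distance zero when duplicates exist, else in column 0).
    n_rows = np.arange(n)
    m = kq - 1
    keep_idx = np.empty((n, m), dtype=np.int64)
    keep_dist = np.empty((n, m), dtype=float)
    self_pos = np.argmax(idx == n_rows[:, None], axis=1)
    for i in range(n):
        p = self_pos[i]
        keep_idx[i] = np.concatenate([idx[i, :p], idx[i, p + 1 :]])
        keep_dist[i] = np.concatenate([dist[i, :p], dist[i, p + 1 :]])

    if m > maxk:
        # rows where the first dropped candidate ties the last kept one
        # need an exact tie-resolved neighbor set: fetch every point at
        # the boundary distance and re-sort by (distance, id)
        risky = np.flatnonzero(keep_dist[:, maxk] == keep_dist[:, maxk - 1])
        for i in risky:
            radius = keep_dist[i, maxk - 1] * (1 + 1e-12) + 1e-300
            rd, rj = nn.radius_neighbors(cloud.coords[i : i + 1], radius=radius)
            rd, rj = rd[0], rj[0].astype(np.int64)
            notself = rj != i
            rd, rj = rd[notself], rj[notself]
            order = np.lexsort((rj, rd))[:maxk]
            keep_dist[i, : len(order)] = rd[order]
            keep_idx[i, : len(order)] = rj[order]
    return NeighborGraph(
        keep_idx[:, :maxk], keep_dist[:, :maxk],
        metric_name="euclidean", coords=cloud.coords,
    )


def _looks_square(d: np.ndarray, atol: float) -> bool:
    return (
        d.ndim == 2
        and d.shape[0] == d.shape[1]
        and np.all(np.isfinite(d))
        and np.max(np.abs(d - d.T)) <= atol
        and np.max(np.abs(np.diag(d))) <= atol
    )


def from_distances(
    dists: np.ndarray,
    maxk: int | None = None,
    *,
    kind: str = "auto",
    atol: float = 1e-8,
    metric_name: str = "precomputed",
) -> NeighborGraph:
    """Build the graph from precomputed distances.

    ``dists`` is either a square symmetric matrix with zero diagonal, or a
    triplet array of rows (i, j, d) with 0-based integer ids; the symmetric
    closure is applied to triplets, and pairs never listed are treated as
    infinitely far apart.  ``kind`` is "square", "triplets", or "auto"
    (a valid symmetric zero-diagonal square matrix wins; a 3-column array
    that is not one is read as triplets).
    """
    dists = np.asarray(dists, dtype=float)
    if kind not in ("auto", "square", "triplets"):
        raise ValueError("kind must be 'auto', 'square' or 'triplets'")
    if kind == "auto":
        if _looks_square(dists, atol):
            kind = "square"
        elif dists.ndim == 2 and dists.shape[1] == 3:
            kind = "triplets"
        else:
            kind = "square"  # let the square validation report the issue
    if kind == "triplets":
        if dists.ndim != 2 or dists.shape[1] != 3:
            raise ValueError("triplet input must be an (n_pairs, 3) array")
        dmat = _triplets_to_square(dists)
    elif dists.ndim == 2 and dists.shape[0] == dists.shape[1]:
        dmat = dists.copy()
        if np.any(~np.isfinite(dmat)):
            raise ValueError("non-finite distance in matrix")
        if np.max(np.abs(dmat - dmat.T)) > atol:
            raise ValueError("distance matrix is not symmetric within tolerance")
        dmat = 0.5 * (dmat + dmat.T)
        if np.any(np.abs(np.diag(dmat)) > atol):
            raise ValueError("distance matrix diagonal must be zero")
        np.fill_diagonal(dmat, 0.0)
    else:
        raise ValueError("expected a square matrix or an (i, j, d) triplet array")
    if np.any(dmat < 0):
        raise ValueError("negative distance")

    n = dmat.shape[0]
    maxk = _resolve_maxk(maxk, n)
    ids = np.arange(n)
    off = dmat + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    order = np.lexsort((np.broadcast_to(ids, (n, n)), off), axis=1)[:, :maxk]
    rows = ids[:, None]
    nn_dist = off[rows, order]
    if np.any(~np.isfinite(nn_dist)):
        raise ValueError("maxk exceeds the number of specified neighbors for some point")
    full = dmat if np.all(np.isfinite(dmat)) else None
    return NeighborGraph(order, nn_dist, metric_name=metric_name, full_dist=full)


def _triplets_to_square(trip: np.ndarray) -> np.ndarray:
    i = trip[:, 0]
    j = trip[:, 1]
    if np.any(i != np.round(i)) or np.any(j != np.round(j)):
        raise ValueError("triplet ids must be integers")
    i = i.astype(np.int64)
    j = j.astype(np.int64)
    d = trip[:, 2].astype(float)
    if np.any(i < 0) or np.any(j < 0):
        raise ValueError("triplet ids must be nonnegative")
    n = int(max(i.max(), j.max())) + 1
    dmat = np.full((n, n), np.inf)
    np.fill_diagonal(dmat, 0.0)
    dmat[i, j] = d
    dmat[j, i] = d
    return dmat


def remove_duplicates(
    cloud: PointCloud, tol: float = 0.0
) -> tuple[PointCloud, np.ndarray]:
    """Collapse groups of (near-)coincident points to one representative.

    Points closer than ``tol`` are linked; each connected group keeps its
    lowest-id member.  A first-neighbor distance of zero breaks every
    log-ratio downstream, so estimators require a duplicate-free cloud.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    coords = cloud.coords
    n = cloud.n_points

    if tol == 0.0:
        _, rep = np.unique(coords, axis=0, return_inverse=True)
        labels = rep
    else:
        nn = NearestNeighbors(radius=tol)
        nn.fit(coords)
        neigh = nn.radius_neighbors(coords, return_distance=False)
        rows = np.concatenate([np.full(len(v), i) for i, v in enumerate(neigh)])
        cols = np.concatenate(neigh) if len(rows) else np.array([], dtype=int)
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)

    keep = np.full(np.max(labels) + 1, -1, dtype=np.int64)
    for i in range(n):  # lowest id per group
        if keep[labels[i]] == -1:
            keep[labels[i]] = i
    keep_ids = np.sort(keep)
    removed = np.setdiff1d(np.arange(n), keep_ids)
    if len(keep_ids) < 2:
        raise ValueError("degenerate dataset: all points identical within tol")
    return PointCloud(coords[keep_ids]), removed


def rank_matrix(graph: NeighborGraph) -> RankMatrix:
    """Distance ranks of the listed neighbors (1 = nearest).

    Rows of a NeighborGraph are already sorted by (distance, id), so the
    m-th listed neighbor has rank m+1 under the same tie-break.
    """
    if graph.maxk >= 1 and np.any(graph.nn_dist[:, 0] == 0):
        warnings.warn("graph contains zero first-neighbor distances (duplicates?)")
    ranks = np.broadcast_to(
        np.arange(1, graph.maxk + 1), (graph.n_points, graph.maxk)
    ).copy()
    return RankMatrix(ranks)


# ---------------------------------------------------------------- file I/O


def _sniff_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # whitespace


def read_coordinates(path, header: bool = False) -> PointCloud:
    """Read a delimited coordinate file (rows = points; comma/tab/space)."""
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    data = np.loadtxt(path, delimiter=delim, skiprows=1 if header else 0, ndmin=2)
    return PointCloud(data)


def read_distances(path, kind: str = "square", maxk: int | None = None) -> NeighborGraph:
    """Read precomputed distances: 'square' matrix or 'triplets' (i, j, d)."""
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    data = np.loadtxt(path, delimiter=delim, ndmin=2)
    return from_distances(data, maxk=maxk, kind=kind)


def write_graph_tsv(graph: NeighborGraph, path) -> None:
    """Export as TSV: point, neighbor, rank, distance."""
    ranks = rank_matrix(graph).ranks
    with open(path, "w") as fh:
        fh.write("point\tneighbor\trank\tdistance\n")
        for i in range(graph.n_points):
            for m in range(graph.maxk):
                fh.write(
                    f"{i}\t{graph.nn_index[i, m]}\t{ranks[i, m]}\t"
                    f"{graph.nn_dist[i, m]:.17g}\n"
                )


def brute_force_graph(cloud: PointCloud, maxk: int) -> NeighborGraph:
    """Reference O(N^2) construction: full distance matrix, lexsort, truncate.

    Used as the oracle in tests and as the high-D brute path's ground
    truth; kept public because it is handy for small exact computations.
    """
    d = cdist(cloud.coords, cloud.coords)
    return from_distances(d, maxk=maxk, metric_name="euclidean")
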