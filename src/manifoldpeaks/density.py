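"""kNN and point-adaptive kNN (PAk) density estimation on the manifold.

Both estimators turn neighbor distances into densities through the
volume of the neighborhood measured *on the intrinsic manifold*: volumes
use the intrinsic dimension d (typically a rounded scan plateau from
`id_estimation`), never the embedding dimension, so positional
information is not diluted along directions orthogonal to the manifold.

kNN fixes one k for every point and assumes the density exactly constant
over the k-neighborhood.  PAk chooses k point by point — growing the
neighborhood while a likelihood-ratio test accepts local homogeneity —
and then fits, in each adapted neighborhood, a log-density with a linear
correction term, which captures small density variations and markedly
improves behavior where the density changes over short distances.

Densities are returned as F_i = ln rho_i with rho normalized per point
(the 1/N convention of the kNN estimator); downstream clustering only
ever uses differences of F, so the global additive constant is
immaterial there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .neighbors import NeighborGraph

# Homogeneity test threshold: chi^2_1 upper quantile at p = 1e-6.
DEFAULT_D_THR = 23.928
K_MIN = 4

__all__ = [
    "DensityEstimate",
    "ShellGeometry",
    "unit_ball_volume",
    "knn_density",
    "adaptive_k",
    "pak_density",
]


@dataclass(frozen=True)
class DensityEstimate:
    """Per-point log-density with its error and neighborhood size.

    log_den: F_i = ln rho_i (points per unit intrinsic volume, 1/N norm).
    err: sigma_i, the statistical error on F_i.
    k_hat: neighborhood size actually used at each point.
    slope: PAk linear log-density correction a_i (zero for plain kNN).
    """

    log_den: np.ndarray
    err: np.ndarray
    k_hat: np.ndarray
    slope: np.ndarray
    method: str
    id_used: float

    def __post_init__(self):
        for name in ("log_den", "err", "slope"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "k_hat", np.asarray(self.k_hat, dtype=np.int64))
        if not np.all(np.isfinite(self.log_den)):
            raise ValueError("log-density must be finite")
        if np.any(self.err <= 0):
            raise ValueError("errors must be positive")

    @property
    def n_points(self) -> int:
        return len(self.log_den)


@dataclass(frozen=True)
class ShellGeometry:
    """Hyperspherical shell volumes between consecutive neighbors.

    v[i, l-1] = omega_d * (r_{i,l}^d - r_{i,l-1}^d) with r_{i,0} = 0, so a
    row prefix sums to the full ball volume omega_d r_{i,k}^d.
    """

    id_used: float
    omega: float
    shell_volumes: np.ndarray


def unit_ball_volume(d: float) -> float:
    """Volume of the unit ball in R^d, omega_d = pi^(d/2) / Gamma(d/2 + 1).

    d may be any positive real (intrinsic dimensions need not be integer).
    """
    if not d > 0:
        raise ValueError("dimension must be positive")
    return float(np.exp(0.5 * d * np.log(np.pi) - gammaln(0.5 * d + 1.0)))


def shell_geometry(graph: NeighborGraph, id_used: float) -> ShellGeometry:
    omega = unit_ball_volume(id_used)
    rd = graph.nn_dist**id_used
    v = omega * np.diff(rd, axis=1, prepend=0.0)
    return ShellGeometry(id_used, omega, v)


def knn_density(graph: NeighborGraph, k: int, id_used: float) -> DensityEstimate:
    """Fixed-k kNN density: rho_i = (1/N) k / (omega_d r_{i,k}^d).

    The error on ln rho is 1/sqrt(k) (Poisson count in the ball).
    """
    if not 1 <= k <= graph.maxk:
        raise ValueError(f"need 1 <= k <= maxk (got k={k}, maxk={graph.maxk})")
    n = graph.n_points
    r = graph.nn_dist[:, k - 1]
    if np.any(r == 0):
        raise ValueError("zero k-th neighbor distance: remove duplicates first")
    omega = unit_ball_volume(id_used)
    log_den = np.log(k) - np.log(n) - np.log(omega) - id_used * np.log(r)
    kvec = np.full(n, k, dtype=np.int64)
    return DensityEstimate(
        log_den, np.full(n, 1.0 / np.sqrt(k)), kvec, np.zeros(n), "knn", id_used
    )


def likelihood_ratio_stat(v_i: np.ndarray, v_j: np.ndarray, k: int) -> np.ndarray:
    """Homogeneity statistic for two k-neighborhoods of volumes V_i, V_j.

    Twice the log-likelihood-ratio between one shared constant density
    and two free constant densities, for k points observed in each
    volume:  D_k = 2 k ln[ (V_i + V_j)^2 / (4 V_i V_j) ].  Asymptotically
    chi^2 with 1 dof when the two densities are equal.
    """
    return 2.0 * k * np.log((v_i + v_j) ** 2 / (4.0 * v_i * v_j))


def adaptive_k(
    graph: NeighborGraph, id_used: float, d_thr: float = DEFAULT_D_THR
) -> np.ndarray:
    """Per-point neighborhood size chosen by the homogeneity test.

    Starting from k = K_MIN, the neighborhood of each point i grows while
    the constant-density hypothesis between i and its (k+1)-th neighbor j
    survives the likelihood-ratio test (D_k < d_thr); k_hat_i is the last
    accepted size, up to maxk.  Points in smoothly varying regions keep
    large neighborhoods; points near sharp density changes stop early.
    """
    if id_used <= 0:
        raise ValueError("id_used must be positive")
    if graph.maxk <= K_MIN:
        raise ValueError(f"maxk must exceed k_min = {K_MIN}")
    n, maxk = graph.n_points, graph.maxk
    r = graph.nn_dist
    if np.any(r[:, 0] == 0):
        raise ValueError("duplicate points present")
    rd = r**id_used  # volumes up to the common omega factor, which cancels

    k_hat = np.full(n, maxk, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    for k in range(K_MIN, maxk):
        j = graph.nn_index[:, k]  # the (k+1)-th neighbor
        d_k = likelihood_ratio_stat(rd[:, k - 1], rd[j, k - 1], k)
        reject = alive & (d_k >= d_thr)
        # first rejection freezes the point at the last accepted size
        k_hat[reject] = max(k - 1, K_MIN)
        alive &= ~reject
        if not alive.any():
            break
    return k_hat


def _newton_shell_fit(
    v: np.ndarray,
    k_hat: np.ndarray,
    fix_slope: bool = False,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Vectorized Newton maximization of the shell log-likelihood.

    Per point, with shells l = 1..k_hat and volumes v_l, maximizes
        L(F, a) = sum_l [ F + a l - v_l exp(F + a l) ]
    (Poisson model: one point per shell, rate v_l rho e^{a l}).  Returns
    (F, a, converged).  With fix_slope the slope is pinned at 0 and the
    maximizer is the closed-form kNN value F = ln(k / sum v), iterated
    anyway for uniformity.
    """
    n, maxk = v.shape
    ls = np.arange(1, maxk + 1, dtype=float)
    mask = ls[None, :] <= k_hat[:, None]
    vm = np.where(mask, v, 0.0)
    k = k_hat.astype(float)
    t_l = np.where(mask, ls[None, :], 0.0)
    sum_l = t_l.sum(axis=1)

    f = np.log(k / vm.sum(axis=1))  # kNN init
    a = np.zeros(n)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        expo = np.clip(f[:, None] + a[:, None] * t_l, -700, 700)
        w = vm * np.exp(expo) * mask
        s0 = w.sum(axis=1)
        s1 = (w * t_l).sum(axis=1)
        g_f = k - s0
        g_a = sum_l - s1
        if fix_slope:
            g_a = np.zeros(n)
        done = (np.abs(g_f) < tol) & (np.abs(g_a) < tol)
        converged |= done
        if converged.all():
            break
        if fix_slope:
            step_f = g_f / np.maximum(s0, 1e-300)
            f = f + np.clip(step_f, -2.0, 2.0)
            continue
        s2 = (w * t_l**2).sum(axis=1)
        det = s0 * s2 - s1**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step_f = (s2 * g_f - s1 * g_a) / det
        step_a = (s0 * g_a - s1 * g_f) / det
        # damp large steps: keeps the iteration inside the basin
        f = f + np.clip(step_f, -2.0, 2.0)
        a = a + np.clip(step_a, -2.0, 2.0)
    return f, a, converged


def pak_density(
    graph: NeighborGraph,
    id_used: float,
    d_thr: float = DEFAULT_D_THR,
    k_hat: np.ndarray | None = None,
) -> DensityEstimate:
    """Point-adaptive kNN density with a linear log-density correction.

    For each point, the neighborhood size k_hat_i from `adaptive_k` and a
    two-parameter fit (F_i, a_i) of the shell occupancies: F_i is the
    log-density at the point, a_i the local log-density slope across
    shells.  The error is sigma_i = sqrt((4 k_hat + 2) / (k_hat (k_hat - 1))),
    the asymptotic std of the two-parameter maximum-likelihood F.

    Points whose Newton iteration fails to converge (rare, degenerate
    shell patterns) fall back to the kNN value at k_hat_i with a warning.
    """
    if k_hat is None:
        k_hat = adaptive_k(graph, id_used, d_thr)
    geom = shell_geometry(graph, id_used)
    if np.any(geom.shell_volumes[graph.nn_dist > 0] <= 0):
        raise ValueError("non-positive shell volume: remove duplicates first")
    n = graph.n_points
    f, a, ok = _newton_shell_fit(geom.shell_volumes, k_hat)
    if not ok.all():
        bad = np.flatnonzero(~ok)
        warnings.warn(
            f"PAk Newton did not converge for {len(bad)} point(s); "
            "falling back to kNN at k_hat there"
        )
        vsum = np.cumsum(geom.shell_volumes, axis=1)[bad, k_hat[bad] - 1]
        f[bad] = np.log(k_hat[bad] / vsum)
        a[bad] = 0.0
    kf = k_hat.astype(float)
    err = np.sqrt((4.0 * kf + 2.0) / (kf * (kf - 1.0)))
    # shift to the kNN 1/N convention: exp(F) integrates like a density
    return DensityEstimate(f - np.log(n), err, k_hat, a, "pak", id_used)
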