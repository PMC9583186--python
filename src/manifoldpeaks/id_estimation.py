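"""Intrinsic-dimension estimation from neighbor-distance ratios.

For points sampled from a locally uniform density on a d-dimensional
manifold, the ratio mu_i = r_{i,2} / r_{i,1} of the distances to the
second and first nearest neighbor follows a Pareto law

    p(mu | d) = d * mu^-(d + 1),   mu > 1,

which depends only on the intrinsic dimension d and not on the density.
The 2NN family estimates d from the sample {mu_i} by maximum likelihood,
Bayesian inference, or regression on the empirical CDF.  Because a
single ratio probes only the first two neighbor shells, two scan
strategies probe the ID as a function of length scale: decimation
(subsample, re-estimate; larger typical distances, larger variance) and
Gride (generalized ratios r_{2k}/r_k of the same dataset; larger scales
with no subsampling).

Scale selection is deliberately left to the user: the scans return the
full profile and the caller picks the plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import betaln

from .neighbors import NeighborGraph, PointCloud, build_neighbor_graph

__all__ = [
    "MuSample",
    "IdEstimate",
    "IdScan",
    "compute_mu",
    "id_2nn_mle",
    "id_2nn_regression",
    "id_2nn_bayes",
    "id_decimation_scan",
    "id_gride_scan",
]


@dataclass(frozen=True)
class MuSample:
    """Per-point distance ratios mu_i = r_{i,n2} / r_{i,n1} (dimensionless)."""

    mu: np.ndarray
    n1: int = 1
    n2: int = 2
    scale: float = float("nan")  # mean r_{n2}, in input units

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim != 1 or len(mu) == 0:
            raise ValueError("mu must be a nonempty 1-D array")
        if np.any(mu < 1):
            raise ValueError("every mu must be >= 1 (r_{n2} >= r_{n1})")
        object.__setattr__(self, "mu", mu)

    @property
    def n(self) -> int:
        return len(self.mu)


@dataclass(frozen=True)
class IdEstimate:
    """An intrinsic-dimension estimate with its error and probing scale."""

    id: float
    err: float
    scale: float
    n_used: int
    method: str = "2nn_mle"

    def __post_init__(self):
        if not self.id > 0:
            raise ValueError("id must be positive")
        if self.err < 0:
            raise ValueError("err must be nonnegative")


@dataclass(frozen=True)
class IdScan:
    """ID estimates ordered by strictly increasing probing scale."""

    estimates: tuple
    method: str

    def __post_init__(self):
        scales = np.array([e.scale for e in self.estimates])
        if len(scales) > 1 and not np.all(np.diff(scales) > 0):
            raise ValueError("scan scales must be strictly increasing")

    @property
    def ids(self) -> np.ndarray:
        return np.array([e.id for e in self.estimates])

    @property
    def errs(self) -> np.ndarray:
        return np.array([e.err for e in self.estimates])

    @property
    def scales(self) -> np.ndarray:
        return np.array([e.scale for e in self.estimates])


def compute_mu(graph: NeighborGraph, n1: int = 1, n2: int = 2) -> MuSample:
    """Ratios of the n2-th to the n1-th neighbor distance, per point."""
    if not (1 <= n1 < n2 <= graph.maxk):
        raise ValueError(f"need 1 <= n1 < n2 <= maxk (got n1={n1}, n2={n2}, maxk={graph.maxk})")
    r1 = graph.nn_dist[:, n1 - 1]
    r2 = graph.nn_dist[:, n2 - 1]
    if np.any(r1 == 0):
        raise ValueError("duplicate points present: zero neighbor distance")
    return MuSample(r2 / r1, n1=n1, n2=n2, scale=float(np.mean(r2)))


def _check_2nn(sample: MuSample) -> float:
    if (sample.n1, sample.n2) != (1, 2):
        raise ValueError("2NN estimators require (n1, n2) = (1, 2)")
    s = float(np.sum(np.log(sample.mu)))
    if s <= 0:
        raise ValueError("sum of log ratios is zero: degenerate sample (duplicates?)")
    return s


def id_2nn_mle(sample: MuSample) -> IdEstimate:
    """Maximum-likelihood 2NN estimate: d = n / sum(ln mu)."""
    s = _check_2nn(sample)
    n = sample.n
    d = n / s
    return IdEstimate(d, d / np.sqrt(n), sample.scale, n, method="2nn_mle")


def id_2nn_regression(sample: MuSample, discard_fraction: float = 0.1) -> IdEstimate:
    """Least-squares 2NN estimate on the log-transformed empirical CDF.

    Under the Pareto law, -ln(1 - F(mu)) = d ln(mu); fitting a line
    through the origin on the order statistics recovers d.  The largest
    ``discard_fraction`` of the ratios is dropped: the top of the
    empirical CDF is noise-dominated (and F = 1 maps to infinity).
    """
    _check_2nn(sample)
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    mu = np.sort(sample.mu)
    n = len(mu)
    m = n - max(1, int(np.floor(discard_fraction * n)))
    if m < 10:
        raise ValueError("fewer than 10 points retained for the regression")
    f = np.arange(1, m + 1) / n
    x = np.log(mu[:m])
    y = -np.log1p(-f)
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate sample: all retained mu equal 1")
    d = float(np.dot(x, y)) / sxx
    # CDF residuals are strongly correlated, so the naive regression SE
    # would be absurdly optimistic; report the sampling error of the
    # estimator family, d / sqrt(n), instead.
    err = d / np.sqrt(m)
    return IdEstimate(d, err, sample.scale, m, method="2nn_reg")


def id_2nn_bayes(
    sample: MuSample, prior_shape: float = 1.0, prior_rate: float = 0.0
) -> IdEstimate:
    """Bayesian 2NN estimate with the conjugate Gamma prior on d.

    The Pareto likelihood in d is Gamma-shaped, so a Gamma(shape, rate)
    prior yields the posterior Gamma(shape + n, rate + sum ln mu); the
    point estimate is the posterior mean, the error its standard
    deviation.  Defaults (1, 0) are a flat prior on d > 0.
    """
    if prior_shape <= 0 or prior_rate < 0:
        raise ValueError("need prior_shape > 0 and prior_rate >= 0")
    s = _check_2nn(sample)
    a = prior_shape + sample.n
    b = prior_rate + s
    return IdEstimate(a / b, np.sqrt(a) / b, sample.scale, sample.n, method="2nn_bayes")


def id_decimation_scan(
    data: PointCloud | NeighborGraph | np.ndarray,
    fractions=(1.0, 0.5, 0.25, 0.125),
    n_reps: int = 10,
    seed: int | None = None,
    maxk: int = 2,
) -> IdScan:
    """Probe the ID at increasing scales by random subsampling.

    Keeping a fraction f of the points stretches typical neighbor
    distances by ~ f^(-1/d), so smaller fractions probe larger scales —
    at the cost of variance, reported as the std over ``n_reps``
    independent subsamples.  Fraction 1.0 is the plain full-data 2NN MLE.
    """
    if isinstance(data, NeighborGraph):
        if data.coords is None and data.full_dist is None:
            raise ValueError("decimation needs coordinates or a full distance matrix")
        coords = data.coords
        full = data.full_dist
    else:
        cloud = data if isinstance(data, PointCloud) else PointCloud(data)
        coords = cloud.coords
        full = None
    n = len(coords) if coords is not None else len(full)
    fractions = sorted(set(float(f) for f in fractions), reverse=True)
    if not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if int(round(min(fractions) * n)) < 20:
        raise ValueError("smallest fraction leaves fewer than 20 points")
    if min(fractions) < 1 and seed is None:
        raise ValueError("an explicit seed is required for subsampled fractions")
    rng = np.random.default_rng(seed)

    def _estimate(ids: np.ndarray) -> IdEstimate:
        if coords is not None:
            g = build_neighbor_graph(PointCloud(coords[ids]), maxk=maxk)
        else:
            from .neighbors import from_distances

            g = from_distances(full[np.ix_(ids, ids)], maxk=maxk)
        return id_2nn_mle(compute_mu(g))

    estimates = []
    for f in fractions:
        m = int(round(f * n))
        if f == 1.0:
            est = _estimate(np.arange(n))
            estimates.append(IdEstimate(est.id, est.err, est.scale, est.n_used, "decimation"))
            continue
        reps = [_estimate(rng.choice(n, size=m, replace=False)) for _ in range(n_reps)]
        ids_ = np.array([e.id for e in reps])
        scales = np.array([e.scale for e in reps])
        estimates.append(
            IdEstimate(
                float(np.mean(ids_)),
                float(np.std(ids_, ddof=1)) if n_reps > 1 else float(reps[0].err),
                float(np.mean(scales)),
                m,
                "decimation",
            )
        )
    estimates.sort(key=lambda e: e.scale)
    return IdScan(tuple(estimates), method="decimation")


# ------------------------------------------------------------------ Gride


def _gride_score(d: float, mu: np.ndarray, n1: int) -> float:
    """Derivative in d of the generalized-ratio log-likelihood.

    Written with mu^-d (in (0,1)) so it never overflows:
        score(d) = n/d + (n1-1) sum ln(mu)/(1 - mu^-d) - (2 n1 - 1) sum ln(mu)
    Strictly decreasing in d, hence a unique root.
    """
    lmu = np.log(mu)
    t = np.exp(-d * lmu)  # mu^-d
    return (
        len(mu) / d
        + (n1 - 1) * float(np.sum(lmu / (1.0 - t)))
        - (2 * n1 - 1) * float(np.sum(lmu))
    )


def _gride_fisher(d: float, mu: np.ndarray, n1: int) -> float:
    """Observed Fisher information (-d2 logL / dd2) at d."""
    lmu = np.log(mu)
    t = np.exp(-d * lmu)
    return len(mu) / d**2 + (n1 - 1) * float(np.sum(t * lmu**2 / (1.0 - t) ** 2))


def gride_loglik(d: float, mu: np.ndarray, n1: int) -> float:
    """Generalized-ratio log-likelihood for ratios mu = r_{2 n1} / r_{n1}.

    Density of a single ratio:
        f(mu | d) = d (mu^d - 1)^(n1-1) / [B(n1, n1) mu^((2 n1 - 1) d + 1)]
    which reduces to the Pareto law d mu^-(d+1) at n1 = 1 (B(1,1) = 1).
    """
    lmu = np.log(mu)
    # ln(mu^d - 1) = d ln mu + ln(1 - mu^-d), overflow-safe
    return float(
        len(mu) * (np.log(d) - betaln(n1, n1))
        + (n1 - 1) * np.sum(d * lmu + np.log1p(-np.exp(-d * lmu)))
        - ((2 * n1 - 1) * d + 1) * np.sum(lmu)
    )


def gride_mle(sample: MuSample) -> IdEstimate:
    """Maximize the generalized-ratio likelihood over d for one scan point.

    n1 = 1 reduces algebraically to the 2NN Pareto, so its closed-form
    maximizer is returned directly; for n1 > 1 the score is monotone and
    brentq finds its root in a log-spaced bracket d in [0.01, 1000].
    """
    n1 = sample.n1
    if sample.n2 != 2 * n1:
        raise ValueError("Gride requires n2 = 2 * n1")
    mu = sample.mu
    pos = mu[mu > 1]
    if len(pos) == 0:
        raise ValueError("all ratios equal 1: degenerate sample")
    if n1 == 1:
        s = float(np.sum(np.log(mu)))
        d = len(mu) / s
    else:
        lo, hi = 0.01, 1000.0
        flo, fhi = _gride_score(lo, mu, n1), _gride_score(hi, mu, n1)
        if flo < 0 or fhi > 0:
            raise RuntimeError(
                "Gride optimizer bracket failure: score at d=0.01 is "
                f"{flo:.3g}, at d=1000 is {fhi:.3g}; the sample may be degenerate"
            )
        d = brentq(_gride_score, lo, hi, args=(mu, n1), xtol=1e-12, rtol=1e-12)
    err = 1.0 / np.sqrt(_gride_fisher(d, mu, n1))
    return IdEstimate(float(d), float(err), sample.scale, len(mu), method="gride")


def id_gride_scan(graph: NeighborGraph, n1_list=(1, 2, 4, 8, 16)) -> IdScan:
    """Gride scan over a doubling schedule of neighbor orders.

    Each scan point uses ratios mu_i = r_{i, 2 n1} / r_{i, n1}; larger n1
    probes larger scales on the same dataset, with no subsampling.
    """
    n1_list = sorted(set(int(v) for v in n1_list))
    if n1_list[0] < 1:
        raise ValueError("n1 values must be >= 1")
    if 2 * n1_list[-1] > graph.maxk:
        raise ValueError(
            f"need 2*max(n1) <= maxk (got max n1 {n1_list[-1]}, maxk {graph.maxk})"
        )
    estimates = [gride_mle(compute_mu(graph, n1, 2 * n1)) for n1 in n1_list]
    estimates.sort(key=lambda e: e.scale)
    return IdScan(tuple(estimates), method="gride")


def plateau_estimate(scan: IdScan) -> IdEstimate:
    """Most scale-consistent value of a scan: the adjacent pair whose
    estimates differ least (relatively), averaged.

    A convenience for non-interactive use; plateau selection is otherwise
    left to inspection of the full scan.
    """
    ids = scan.ids
    if len(ids) == 1:
        return scan.estimates[0]
    rel = np.abs(np.diff(ids)) / np.minimum(ids[:-1], ids[1:])
    i = int(np.argmin(rel))
    a, b = scan.estimates[i], scan.estimates[i + 1]
    return IdEstimate(
        0.5 * (a.id + b.id),
        0.5 * np.hypot(a.err, b.err),
        0.5 * (a.scale + b.scale),
        min(a.n_used, b.n_used),
        method=scan.method,
    )
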