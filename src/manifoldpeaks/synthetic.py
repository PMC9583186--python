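"""Seeded synthetic datasets with known ground truth.

Every generator here is a pure function of its parameters and seed, and
returns the generative truth (labels, manifold dimension, log-density)
alongside the coordinates.  The truth fields exist for tests and
benchmarks only: estimators never see them.

The flagship fixture is the Möbius benchmark: an 8-mode Gaussian
mixture on a 2D rectangular strip, twisted through the standard Möbius
embedding into 3D, rotated into a 50-dimensional ambient space and
perturbed with isotropic Gaussian noise.  It is topologically
non-trivial (the strip is one-sided, so no global 2D parametrization
exists), which defeats projection-based methods while the distance-based
estimators still read the intrinsic dimension (2) and the eight density
peaks directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from .id_estimation import MuSample
from .neighbors import PointCloud

__all__ = [
    "SyntheticDataset",
    "make_uniform_hypercube",
    "make_pareto_mu",
    "make_gaussian_mixture",
    "make_mobius_benchmark",
    "MOBIUS_MODES",
]


@dataclass(frozen=True)
class SyntheticDataset:
    """Coordinates plus generative truth (never consumed by estimators)."""

    cloud: PointCloud
    true_labels: np.ndarray | None
    true_id: float
    true_logden: np.ndarray | None

    @property
    def coords(self) -> np.ndarray:
        return self.cloud.coords


def make_uniform_hypercube(n: int, d: int, seed: int) -> SyntheticDataset:
    """n i.i.d. uniform points in [0, 1]^d (constant density, ID = d)."""
    if n < 20:
        raise ValueError("need n >= 20")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(size=(n, d))
    return SyntheticDataset(PointCloud(coords), None, float(d), np.zeros(n))


def make_pareto_mu(n: int, id_true: float, seed: int) -> MuSample:
    """Neighbor ratios drawn from the exact 2NN Pareto law.

    Inverse-CDF sampling: mu = (1 - u)^(-1/d), u ~ U(0, 1); E[ln mu] = 1/d.
    """
    if id_true <= 0:
        raise ValueError("id_true must be positive")
    u = np.random.default_rng(seed).uniform(size=n)
    return MuSample((1.0 - u) ** (-1.0 / id_true), n1=1, n2=2)


def make_gaussian_mixture(
    n: int,
    centers,
    sigmas,
    weights,
    seed: int,
) -> SyntheticDataset:
    """Labeled draw from a spherical Gaussian mixture with analytic truth.

    ``centers`` is a C x d matrix, ``sigmas`` and ``weights`` length-C;
    weights must sum to 1.  true_logden is the exact mixture log-pdf.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    sigmas = np.asarray(sigmas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if len(sigmas) != len(centers) or len(weights) != len(centers):
        raise ValueError("centers, sigmas, weights must have equal length")
    rng = np.random.default_rng(seed)
    d = centers.shape[1]
    counts = rng.multinomial(n, weights)
    coords = np.empty((n, d))
    labels = np.empty(n, dtype=np.int64)
    start = 0
    for c, m in enumerate(counts):
        coords[start : start + m] = rng.normal(centers[c], sigmas[c], size=(m, d))
        labels[start : start + m] = c
        start += m
    perm = rng.permutation(n)
    coords, labels = coords[perm], labels[perm]
    dens = np.zeros(n)
    for c in range(len(centers)):
        dens += weights[c] * multivariate_normal.pdf(
            coords, mean=centers[c], cov=sigmas[c] ** 2
        )
    return SyntheticDataset(PointCloud(coords), labels, float(d), np.log(dens))


# Eight modes on the (u, v) strip, u in [0, 2pi), |v| <= ~0.35.
# Adjacent modes alternate sides of the strip; the closest pair is
# ~0.86 apart while the largest component spread is 0.12, i.e. > 7
# sigma separation — ground-truth clusters are unambiguous.
MOBIUS_MODES = {
    "u": (2.0 * np.arange(8) + 1.0) * np.pi / 8.0,
    "v": np.where(np.arange(8) % 2 == 0, 0.18, -0.18),
    "sigma_u": 0.12,
    "sigma_v": 0.06,
}


def mobius_map(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Standard Möbius embedding of the strip into 3D (mid-circle radius 1):
    (u, v) and (u + 2pi, -v) land on the same point."""
    w = 1.0 + v * np.cos(u / 2.0)
    return np.column_stack([w * np.cos(u), w * np.sin(u), v * np.sin(u / 2.0)])


def make_mobius_benchmark(
    n: int = 10_000,
    n_embed: int = 50,
    noise_sigma: float = 2e-4,
    seed: int = 0,
) -> SyntheticDataset:
    """The topologically complex benchmark: 8 density clusters on a 2D
    sheet twisted into a Möbius strip inside a noisy 50D space.

    (u, v) pairs are drawn from the 8-mode mixture `MOBIUS_MODES`,
    mapped through the Möbius embedding, padded to ``n_embed``
    dimensions, rotated by a seeded random orthogonal matrix (so the
    manifold is not axis-aligned) and perturbed with isotropic Gaussian
    noise of standard deviation ``noise_sigma`` per coordinate.  The
    default noise (total RMS displacement ~0.0014, i.e. ~0.14% of the
    strip width) fills all 50 coordinates while staying below typical
    first-neighbor spacings, so the manifold remains two-dimensional at
    the scales the estimators probe.

    true_logden is the mixture log-density in strip coordinates (the
    embedding is close to isometric for |v| small, so it tracks the
    on-manifold density well).
    """
    if n < 2000:
        raise ValueError("need n >= 2000 for a meaningful benchmark")
    rng = np.random.default_rng(seed)
    modes_u = MOBIUS_MODES["u"]
    modes_v = MOBIUS_MODES["v"]
    su, sv = MOBIUS_MODES["sigma_u"], MOBIUS_MODES["sigma_v"]
    counts = rng.multinomial(n, np.full(8, 1.0 / 8.0))
    u = np.empty(n)
    v = np.empty(n)
    labels = np.empty(n, dtype=np.int64)
    start = 0
    for c in range(8):
        m = counts[c]
        u[start : start + m] = rng.normal(modes_u[c], su, size=m)
        v[start : start + m] = rng.normal(modes_v[c], sv, size=m)
        labels[start : start + m] = c
        start += m
    perm = rng.permutation(n)
    u, v, labels = u[perm], v[perm], labels[perm]

    xyz = mobius_map(u, v)
    padded = np.zeros((n, n_embed))
    padded[:, :3] = xyz
    # seeded random rotation: QR of a Gaussian matrix, sign-fixed
    q, r = np.linalg.qr(rng.normal(size=(n_embed, n_embed)))
    q *= np.sign(np.diag(r))
    coords = padded @ q.T + rng.normal(0.0, noise_sigma, size=(n, n_embed))

    logden = np.zeros(n)
    for c in range(8):
        # wrap u-differences onto the strip's periodic direction
        du = np.angle(np.exp(1j * (u - modes_u[c])))
        dv = v - modes_v[c]
        logden += (1.0 / 8.0) * np.exp(
            -0.5 * (du / su) ** 2 - 0.5 * (dv / sv) ** 2
        ) / (2.0 * np.pi * su * sv)
    return SyntheticDataset(PointCloud(coords), labels, 2.0, np.log(logden))
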