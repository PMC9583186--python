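"""Density-peak clustering against brute-force oracles and generative truth."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import manifoldpeaks as mp
from conftest import best_label_agreement


def _manual_density(log_den, k_hat, err=None):
    log_den = np.asarray(log_den, dtype=float)
    n = len(log_den)
    k_hat = np.full(n, k_hat) if np.isscalar(k_hat) else np.asarray(k_hat)
    err = np.ones(n) if err is None else np.asarray(err, dtype=float)
    return mp.DensityEstimate(log_den, err, k_hat, np.zeros(n), "manual", 1.0)


def brute_delta(coords, f):
    """Independent O(N^2) evaluation of delta (ties: lower id is higher)."""
    d = cdist(coords, coords)
    n = len(coords)
    delta = np.empty(n)
    nneigh = np.full(n, -1)
    for i in range(n):
        higher = [j for j in range(n) if f[j] > f[i] or (f[j] == f[i] and j < i)]
        if not higher:
            delta[i] = d[i].max()
            continue
        best = min((d[i, j], j) for j in higher)
        delta[i], nneigh[i] = best
    return delta, nneigh


def test_decision_graph_hand_example():
    coords = np.array([[0.0], [1.0], [3.0]])
    g = mp.build_neighbor_graph(coords, maxk=2)
    dg = mp.decision_graph(g, _manual_density([3.0, 2.0, 1.0], 2))
    assert dg.delta.tolist() == [3.0, 1.0, 2.0]
    assert dg.nneigh_higher.tolist() == [-1, 0, 1]


def test_decision_graph_matches_bruteforce():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(300, 2))
    g = mp.build_neighbor_graph(coords, maxk=15)  # small maxk forces fallback
    f = rng.normal(size=300)
    dg = mp.decision_graph(g, _manual_density(f, 10))
    delta, nneigh = brute_delta(coords, f)
    assert np.allclose(dg.delta, delta)
    assert np.array_equal(dg.nneigh_higher, nneigh)


def test_global_maximum_has_largest_delta():
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(100, 3))
    f = rng.normal(size=100)
    g = mp.build_neighbor_graph(coords, maxk=30)
    dg = mp.decision_graph(g, _manual_density(f, 20))
    top = np.argmax(f)
    assert dg.delta[top] == dg.delta.max()
    assert dg.nneigh_higher[top] == -1


def test_degenerate_density_rejected():
    g = mp.build_neighbor_graph(np.random.default_rng(2).normal(size=(20, 2)), maxk=5)
    with pytest.raises(ValueError, match="degenerate density"):
        mp.decision_graph(g, _manual_density(np.ones(20), 5))


class TestDpCluster:
    def test_single_center_single_cluster(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(50, 2))
        g = mp.build_neighbor_graph(coords, maxk=20)
        den = mp.knn_density(g, 10, 2.0)
        dg = mp.decision_graph(g, den)
        top = int(np.argmax(den.log_den))
        res = mp.dp_cluster(dg, g, centers=[top])
        assert res.n_clusters == 1
        assert np.all(res.labels == 0)
        assert res.population.tolist() == [50]

    def test_two_blobs_match_generative_labels(self):
        ds = mp.make_gaussian_mixture(
            1000, [[0.0, 0.0], [10.0, 0.0]], [1.0, 1.0], [0.5, 0.5], seed=4
        )
        g = mp.build_neighbor_graph(ds.cloud, maxk=50)
        den = mp.pak_density(g, 2.0)
        dg = mp.decision_graph(g, den)
        # the two density maxima: highest-density point in each half
        left = np.flatnonzero(ds.coords[:, 0] < 5)
        right = np.flatnonzero(ds.coords[:, 0] >= 5)
        centers = [
            int(left[np.argmax(den.log_den[left])]),
            int(right[np.argmax(den.log_den[right])]),
        ]
        res = mp.dp_cluster(dg, g, centers=centers)
        assert res.n_clusters == 2
        assert best_label_agreement(ds.true_labels, res.labels) >= 0.95

    def test_chain_property(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(200, 2))
        g = mp.build_neighbor_graph(coords, maxk=30)
        den = mp.knn_density(g, 15, 2.0)
        dg = mp.decision_graph(g, den)
        centers = np.argsort(den.log_den)[-3:]
        res = mp.dp_cluster(dg, g, centers=centers)
        for i in range(200):
            j = dg.nneigh_higher[i]
            if j >= 0 and i not in centers.tolist():
                assert res.labels[i] == res.labels[j]

    def test_empty_center_set_rejected(self):
        rng = np.random.default_rng(6)
        g = mp.build_neighbor_graph(rng.normal(size=(30, 2)), maxk=10)
        den = mp.knn_density(g, 5, 2.0)
        dg = mp.decision_graph(g, den)
        with pytest.raises(ValueError, match="center"):
            mp.dp_cluster(dg, g, centers=[])


class TestFindSaddles:
    def test_no_mutual_cross_neighbors_no_saddles(self):
        ds = mp.make_gaussian_mixture(
            200, [[0.0, 0.0], [100.0, 0.0]], [1.0, 1.0], [0.5, 0.5], seed=7
        )
        g = mp.build_neighbor_graph(ds.cloud, maxk=20)
        den = mp.knn_density(g, 10, 2.0)
        labels = (ds.coords[:, 0] > 50).astype(np.int64)
        centers = np.array(
            [np.flatnonzero(labels == c)[np.argmax(den.log_den[labels == c])]
             for c in (0, 1)]
        )
        # relabel so each center carries its own cluster
        labels = labels if den.log_den[centers[0]] >= den.log_den[centers[1]] else 1 - labels
        centers = centers if labels[centers[0]] == 0 else centers[::-1]
        sl, se = mp.find_saddles(g, den, labels, centers)
        assert np.all(np.isnan(sl[0, 1]))

    def test_matches_exhaustive_mutual_enumeration(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(40, 2))
        g = mp.build_neighbor_graph(coords, maxk=39)
        den = mp.knn_density(g, 8, 2.0)
        labels = rng.integers(0, 3, size=40).astype(np.int64)
        centers = np.array(
            [np.flatnonzero(labels == c)[np.argmax(den.log_den[labels == c])]
             for c in range(3)]
        )
        for c in range(3):  # force center labels consistent
            labels[centers[c]] = c
        # oracle: enumerate all mutual-k_hat pairs
        k = den.k_hat
        best = {}
        for i in range(40):
            for m in range(k[i]):
                j = g.nn_index[i, m]
                pos = list(g.nn_index[j]).index(i)
                if pos >= k[j] or labels[i] == labels[j] or i in centers:
                    continue
                key = (min(labels[i], labels[j]), max(labels[i], labels[j]))
                if key not in best or den.log_den[i] > best[key]:
                    best[key] = den.log_den[i]
        sl, se = mp.find_saddles(g, den, labels, centers)
        for (a, b), val in best.items():
            assert sl[a, b] == pytest.approx(val)
        for a in range(3):
            for b in range(a + 1, 3):
                if (a, b) not in best:
                    assert np.isnan(sl[a, b])

    def test_saddle_below_both_peaks(self, mobius_graph, mobius_pak):
        res = mp.adp_cluster(mobius_graph, mobius_pak)
        for a in range(res.n_clusters):
            for b in range(res.n_clusters):
                if a != b and np.isfinite(res.saddle_logden[a, b]):
                    assert res.saddle_logden[a, b] <= res.peak_logden[a]
                    assert res.saddle_logden[a, b] <= res.peak_logden[b]


class TestAdpCluster:
    def test_single_gaussian_one_cluster(self):
        ds = mp.make_gaussian_mixture(2000, np.zeros((1, 2)), [1.0], [1.0], seed=9)
        g = mp.build_neighbor_graph(ds.cloud, maxk=100)
        den = mp.pak_density(g, 2.0)
        res = mp.adp_cluster(g, den, z=1.65)
        assert res.n_clusters == 1

    @pytest.mark.parametrize("z", [1.0, 2.0, 3.5, 5.0])
    def test_two_far_gaussians_two_clusters(self, z):
        ds = mp.make_gaussian_mixture(
            1500, [[0.0, 0.0], [15.0, 0.0]], [1.0, 1.0], [0.5, 0.5], seed=10
        )
        g = mp.build_neighbor_graph(ds.cloud, maxk=80)
        den = mp.pak_density(g, 2.0)
        res = mp.adp_cluster(g, den, z=z)
        assert res.n_clusters == 2
        assert best_label_agreement(ds.true_labels, res.labels) >= 0.95

    def test_cluster_count_nonincreasing_in_z(self):
        ds = mp.make_gaussian_mixture(
            1500,
            [[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]],
            [1.0, 1.0, 1.0],
            [1 / 3, 1 / 3, 1 / 3],
            seed=11,
        )
        g = mp.build_neighbor_graph(ds.cloud, maxk=60)
        den = mp.pak_density(g, 2.0)
        counts = [mp.adp_cluster(g, den, z=z).n_clusters for z in range(6)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_surviving_peaks_reproduce_adp_via_dp(self, mobius_graph, mobius_pak):
        res = mp.adp_cluster(mobius_graph, mobius_pak)
        dg = mp.decision_graph(mobius_graph, mobius_pak)
        res_dp = mp.dp_cluster(dg, mobius_graph, centers=res.centers)
        assert np.array_equal(res.labels, res_dp.labels)
        assert np.array_equal(res.centers, res_dp.centers)

    def test_point_permutation_consistency(self):
        ds = mp.make_gaussian_mixture(
            600, [[0.0, 0.0], [12.0, 0.0]], [1.0, 1.0], [0.5, 0.5], seed=12
        )
        g1 = mp.build_neighbor_graph(ds.cloud, maxk=40)
        r1 = mp.adp_cluster(g1, mp.pak_density(g1, 2.0))
        perm = np.random.default_rng(13).permutation(600)
        g2 = mp.build_neighbor_graph(ds.coords[perm], maxk=40)
        r2 = mp.adp_cluster(g2, mp.pak_density(g2, 2.0))
        # labels are numbered by descending peak density in both runs
        assert np.array_equal(r2.labels, r1.labels[perm])

    def test_populations_sum_to_n(self, mobius_graph, mobius_pak):
        res = mp.adp_cluster(mobius_graph, mobius_pak)
        assert res.population.sum() == mobius_graph.n_points
        for c, center in enumerate(res.centers):
            assert res.labels[center] == c


class TestDendrogram:
    def test_two_clusters_one_saddle(self):
        ds = mp.make_gaussian_mixture(
            1000, [[0.0, 0.0], [6.0, 0.0]], [1.0, 1.0], [0.5, 0.5], seed=14
        )
        g = mp.build_neighbor_graph(ds.cloud, maxk=60)
        den = mp.pak_density(g, 2.0)
        res = mp.adp_cluster(g, den, z=1.0)
        assert res.n_clusters == 2
        dendro = mp.dendrogram_summary(res)
        assert len(dendro.peaks) == 2
        assert len(dendro.saddles) == 1
        s = dendro.saddles[0]
        assert s["logden"] < min(p["logden"] for p in dendro.peaks)

    def test_spans_proportional_to_population(self, mobius_graph, mobius_pak):
        res = mp.adp_cluster(mobius_graph, mobius_pak)
        dendro = mp.dendrogram_summary(res)
        widths = []
        edges = [0.0]
        for p in sorted(dendro.peaks, key=lambda p: p["x"]):
            # each peak sits in the middle of its population span
            left = edges[-1]
            widths.append(2 * (p["x"] - left))
            edges.append(left + widths[-1])
        assert np.allclose(
            widths, [p["population"] for p in sorted(dendro.peaks, key=lambda q: q["x"])]
        )

    def test_single_cluster_no_saddles(self):
        ds = mp.make_gaussian_mixture(800, np.zeros((1, 2)), [1.0], [1.0], seed=15)
        g = mp.build_neighbor_graph(ds.cloud, maxk=60)
        res = mp.adp_cluster(g, mp.pak_density(g, 2.0))
        dendro = mp.dendrogram_summary(res)
        assert len(dendro.peaks) == 1
        assert dendro.saddles == []
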