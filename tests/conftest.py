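import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import manifoldpeaks as mp

MOBIUS_SEED = 42


@pytest.fixture(scope="session")
def mobius_bench():
    """The 8-cluster Möbius benchmark at full size, built once."""
    return mp.make_mobius_benchmark(10_000, seed=MOBIUS_SEED)


@pytest.fixture(scope="session")
def mobius_graph(mobius_bench):
    return mp.build_neighbor_graph(mobius_bench.cloud, maxk=100)


@pytest.fixture(scope="session")
def mobius_pak(mobius_graph):
    """PAk density on the benchmark at the pipeline's own ID estimate."""
    scan = mp.id_gride_scan(mobius_graph, (1, 2, 4, 8, 16))
    id_used = round(mp.plateau_estimate(scan).id)
    return mp.pak_density(mobius_graph, float(id_used))


def best_label_agreement(true_labels, pred_labels) -> float:
    """Fraction of points matching under the best cluster<->mode matching."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    c = np.zeros((true_labels.max() + 1, pred_labels.max() + 1), dtype=np.int64)
    np.add.at(c, (true_labels, pred_labels), 1)
    if c.shape[0] > c.shape[1]:
        c = np.pad(c, ((0, 0), (0, c.shape[0] - c.shape[1])))
    rows, cols = linear_sum_assignment(-c)
    return float(c[rows, cols].sum()) / len(true_labels)
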