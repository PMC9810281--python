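import numpy as np
import pytest

from connectoflex.network_io import Connectome, ModulePartition


def make_connectome(weights, signed=False, ids=None):
    w = np.asarray(weights, dtype=float)
    ids = ids or [f"r{i}" for i in range(w.shape[0])]
    return Connectome(weights=w, node_ids=ids, signed=signed)


def make_partition(labels, ids=None):
    labels = np.asarray(labels)
    ids = ids or [f"r{i}" for i in range(labels.size)]
    return ModulePartition(labels=labels, node_ids=ids)


def clique_matrix(n):
    w = np.ones((n, n))
    np.fill_diagonal(w, 0.0)
    return w


def two_cliques_with_bridge(k, bridge_weight=1.0):
    """Two k-cliques joined by a single edge between node 0 and node k."""
    n = 2 * k
    w = np.zeros((n, n))
    w[:k, :k] = clique_matrix(k)
    w[k:, k:] = clique_matrix(k)
    w[0, k] = w[k, 0] = bridge_weight
    return w


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny cohort shared by pipeline tests (slow to build, read-only)."""
    from connectoflex.synthetic_data import CohortSpec, gen_cohort

    spec = CohortSpec(n_subjects=10, n_nodes=32, n_modules=8, t_len=80, seed=99)
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def fast_config():
    from connectoflex.pipeline import AnalysisConfig

    return AnalysisConfig(n_runs=2, n_boot=200, n_perm=120, seed=7)
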