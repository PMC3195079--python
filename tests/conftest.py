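import numpy as np
import pytest

from gcda import Graph, ShrinkageSpec, SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_graph():
    """Path 0-1-2 on three vertices."""
    return Graph(3, frozenset({(0, 1), (1, 2)}))


@pytest.fixture
def small_dataset():
    """Well-separated two-class Gaussian data, p=5, n=60."""
    rng = np.random.default_rng(7)
    n1 = n2 = 30
    X1 = rng.standard_normal((n1, 5)) + np.array([2.0, 0, 0, 0, 0])
    X2 = rng.standard_normal((n2, 5)) - np.array([2.0, 0, 0, 0, 0])
    X = np.vstack([X1, X2])
    y = np.array([1] * n1 + [2] * n2)
    return X, y


@pytest.fixture
def sim_dataset():
    """Graph-generated dataset at moderate size (p=30, n=40)."""
    cfg = SimulationConfig(p=30, n=40, seed=3)
    X, y, (g1, g2) = simulate(cfg)
    return X, y, g1, cfg


@pytest.fixture
def tight_spec():
    """Small grids for fast hyperparameter-selection tests."""
    return ShrinkageSpec(lam=0.1, eps=1.0, lam_grid=(0.0, 0.25, 0.5, 1.0),
                         eps_grid=(0.1, 1.0))


def random_graph(rng, p=None, edge_prob=None) -> Graph:
    """A random graph drawn through plain Bernoulli sampling (test-side
    construction, independent of the package's generator)."""
    p = p or int(rng.integers(3, 25))
    edge_prob = edge_prob if edge_prob is not None else rng.uniform(0.05, 0.5)
    edges = {
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if rng.random() < edge_prob
    }
    return Graph(p, frozenset(edges))
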