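"""Graph-structured Gaussian two-class simulator.

Generates the study conditions used throughout the test-bench: draw an
Erdős–Rényi gene network (one shared network, or one per class), turn each
network into a covariance matrix through the GGM shrinkage target
``Sigma(G) = (L(G) + eps*I)^{-1}``, and sample the two classes as
multivariate Gaussians

    class 1 ~ N(0, Sigma(G1)),        class 2 ~ N(mu, Sigma(G2)),

where ``mu`` is the between-class mean difference.  By default ``mu`` is a
random direction scaled in closed form so that the oracle Bayes accuracy of
the shared-graph problem is 90%: with equal priors the Bayes accuracy is
``Phi(Delta / 2)`` with ``Delta^2 = mu' Sigma^{-1} mu = mu' (L + eps*I) mu``.
A *constant* shift is deliberately not the default: the constant vector
satisfies ``L 1 = 0`` and is therefore an eigenvector of ``Sigma(G)``, a
degenerate direction along which graph-aware and graph-agnostic covariance
shrinkage coincide.

The same module also builds the graph-misspecification ladder: a sequence of
progressively rewired copies of the generating network, each reported with
its achieved structural Hamming distance to the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .covariance import shrinkage_target
from .graphs import Graph, erdos_renyi, laplacian, rewire, structural_hamming_distance

__all__ = ["SimulationConfig", "simulate", "generating_model", "misspecification_ladder"]

#: Default oracle Bayes accuracy for the auto-calibrated mean shift.
DEFAULT_BAYES_ACCURACY = 0.9


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated two-class problem.

    ``mean_shift`` may be a p-vector, a scalar (broadcast to a constant
    vector), or ``None`` for the default auto-calibrated random direction
    (see module docstring).  ``setting`` is ``"shared_graph"`` (linear
    regime, G1 = G2) or ``"two_graphs"`` (quadratic regime).
    """

    p: int = 100
    n: int = 50
    class_balance: float = 0.5
    edge_prob: float = 0.05
    eps: float = 1.0
    mean_shift: object = None
    setting: str = "shared_graph"
    seed: int = 0
    bayes_accuracy: float = DEFAULT_BAYES_ACCURACY

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError(f"p must be >= 2, got {self.p}")
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must be in [0, 1]")
        if self.eps <= 0.0:
            raise ValueError("eps must be positive")
        if self.setting not in ("shared_graph", "two_graphs"):
            raise ValueError(f"unknown setting {self.setting!r}")
        n1, n2 = self.class_sizes
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"class sizes ({n1}, {n2}) must both be >= 2; adjust n/class_balance"
            )

    @property
    def class_sizes(self) -> tuple[int, int]:
        n1 = int(round(self.n * self.class_balance))
        return n1, self.n - n1


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Independent sub-streams so the truth graph does not depend on how much
    # data is drawn afterwards.
    return np.random.default_rng([config.seed, stream])


def _mean_shift_vector(config: SimulationConfig, L1: np.ndarray) -> np.ndarray:
    p = config.p
    if config.mean_shift is None:
        u = _rng(config, 1).standard_normal(p)
        delta = 2.0 * stats.norm.ppf(config.bayes_accuracy)
        prec = L1 + config.eps * np.eye(p)
        scale = delta / np.sqrt(u @ prec @ u)
        return scale * u
    mu = np.asarray(config.mean_shift, dtype=float)
    if mu.ndim == 0:
        return np.full(p, float(mu))
    if mu.shape != (p,):
        raise ValueError(f"mean_shift must be scalar or length-{p} vector")
    return mu


def generating_model(config: SimulationConfig):
    """The ground truth behind :func:`simulate`.

    Returns ``(g1, g2, sigma1, sigma2, mu)``: the generating graphs (the
    same object twice in the shared-graph setting), their GGM covariances,
    and the class-2 mean shift.
    """
    g1 = erdos_renyi(config.p, config.edge_prob, _rng(config, 0))
    if config.setting == "shared_graph":
        g2 = g1
    else:
        g2 = erdos_renyi(config.p, config.edge_prob, _rng(config, 10))
    L1 = laplacian(g1)
    sigma1 = shrinkage_target(L1, config.eps).matrix
    sigma2 = sigma1 if g2 is g1 else shrinkage_target(laplacian(g2), config.eps).matrix
    mu = _mean_shift_vector(config, L1)
    return g1, g2, sigma1, sigma2, mu


def simulate(config: SimulationConfig):
    """Draw one dataset: ``(X, y, (g1, g2))`` with labels 1 and 2.

    Fully reproducible: the same config (including seed) gives bitwise
    identical output.
    """
    g1, g2, sigma1, sigma2, mu = generating_model(config)
    n1, n2 = config.class_sizes
    rng = _rng(config, 2)
    chol1 = np.linalg.cholesky(sigma1)
    chol2 = chol1 if sigma2 is sigma1 else np.linalg.cholesky(sigma2)
    X1 = rng.standard_normal((n1, config.p)) @ chol1.T
    X2 = rng.standard_normal((n2, config.p)) @ chol2.T + mu
    X = np.vstack([X1, X2])
    y = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    return X, y, (g1, g2)


def misspecification_ladder(
    config: SimulationConfig, moves: list[int]
) -> list[tuple[Graph, int]]:
    """Rewiring ladder away from the generating graph.

    Each entry of ``moves`` is a number of edge-rewiring moves applied to
    the truth graph (0 returns the truth itself); each move relocates one
    edge to a uniformly drawn absent pair, so ``k`` moves change the edge
    set by at most ``2k`` slots.  Returns ``(graph, achieved_distance)``
    pairs sorted by achieved structural Hamming distance to the truth.
    """
    if any(moves[i] > moves[i + 1] for i in range(len(moves) - 1)):
        raise ValueError("moves must be sorted non-decreasing")
    truth = generating_model(config)[0]
    if moves and moves[-1] > truth.n_edges:
        raise ValueError(
            f"requested {moves[-1]} moves but the graph has {truth.n_edges} edges"
        )
    out = []
    for k, n_moves in enumerate(moves):
        g = rewire(truth, n_moves, _rng(config, 100 + k)) if n_moves else truth
        out.append((g, structural_hamming_distance(truth, g)))
    out.sort(key=lambda pair: pair[1])
    return out


def write_simulation(config: SimulationConfig, outdir, sep: str = "\t") -> None:
    """Write X/y as delimited text, truth graphs as edge lists, and the
    config as a YAML sidecar — the fixture generator for downstream runs."""
    import os

    import yaml

    from .graphs import write_edge_list
    from .io import LabelledDataset, write_dataset

    os.makedirs(outdir, exist_ok=True)
    X, y, (g1, g2) = simulate(config)
    gene_labels = tuple(f"g{j}" for j in range(config.p))
    g1 = Graph(g1.n_vertices, g1.edges, gene_labels)
    g2 = g1 if g2.edges == g1.edges else Graph(g2.n_vertices, g2.edges, gene_labels)
    ds = LabelledDataset(
        X=X,
        y=y,
        sample_ids=[f"s{i}" for i in range(config.n)],
        gene_ids=[f"g{j}" for j in range(config.p)],
    )
    write_dataset(ds, os.path.join(outdir, "expression.tsv"),
                  os.path.join(outdir, "labels.tsv"), sep=sep)
    write_edge_list(g1, os.path.join(outdir, "graph1.edges"), sep=sep)
    if g2 is not g1:
        write_edge_list(g2, os.path.join(outdir, "graph2.edges"), sep=sep)
    cfg = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
           for k, v in vars(config).items()}
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
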