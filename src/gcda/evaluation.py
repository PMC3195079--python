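"""Monte Carlo cross-validation and the simulation experiment drivers.

The evaluation protocol mirrors the standard small-n microarray benchmark:
the dataset is split at random into a training part (two thirds) and a test
part (the remaining third), the classifier — including its hyperparameter
selection — sees only the training part, and the good-classification rate is
measured on the held-out third.  The split is redrawn ``n_iter`` times
(default 100) and results are reported as mean (sd) percent.  Splits are
stratified by class to avoid degenerate folds at n around 50.

Hyperparameters (shrinkage intensity ``lam`` and target conditioning
``eps``) are selected inside each training fold by internal 10-fold
cross-validation over the grids of :class:`~gcda.covariance.ShrinkageSpec`,
maximizing plain accuracy; ties prefer the smallest ``lam`` then the
smallest ``eps``, i.e. the graph-dominated end of the grid.

Drivers:

* :func:`mccv` — the outer protocol, for any classifier obeying the
  fit/predict contract (a callable that never sees test labels).
* :func:`select_hyperparameters` — the inner grid search.
* :func:`make_gcda_fit_predict` — wires gCDA (with or without inner
  selection) into the contract, caching the graph targets.
* :func:`degradation_experiment` — classification performance as a function
  of the structural Hamming distance between the generating network and the
  network handed to the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from . import classifier as clf
from .covariance import ShrinkageSpec, class_indices, shrinkage_target
from .graphs import Graph, laplacian
from .simulation import SimulationConfig, misspecification_ladder, simulate

__all__ = [
    "PerformanceSummary",
    "mccv",
    "select_hyperparameters",
    "make_gcda_fit_predict",
    "degradation_experiment",
]

logger = logging.getLogger("gcda")


@dataclass
class PerformanceSummary:
    """Per-iteration good-classification rates (percent) with mean and sd."""

    rates: list[float]
    method_id: str = ""
    setting_id: str = ""
    selected_hyperparams: list = field(default_factory=list)

    def __post_init__(self) -> None:
        rates = [float(r) for r in self.rates]
        if any(not 0.0 <= r <= 100.0 for r in rates):
            raise ValueError("rates must be percentages in [0, 100]")
        self.rates = rates

    @property
    def n_iter(self) -> int:
        return len(self.rates)

    @property
    def mean(self) -> float:
        return float(np.mean(self.rates))

    @property
    def sd(self) -> float:
        return float(np.std(self.rates, ddof=1)) if len(self.rates) > 1 else 0.0

    def __str__(self) -> str:  # Table-style "mean (sd)" cell.
        return f"{self.mean:.2f} ({self.sd:.2f})"


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _stratified_split(y, train_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified train/test split; every class keeps >= 2 training
    and >= 1 test samples."""
    _, idx1, idx2 = class_indices(y)
    train, test = [], []
    for idx in (idx1, idx2):
        k = int(round(train_frac * idx.size))
        k = min(max(k, 2), idx.size - 1)
        perm = rng.permutation(idx)
        train.append(perm[:k])
        test.append(perm[k:])
    return np.concatenate(train), np.concatenate(test)


def _stratified_folds(y, k_folds: int, rng) -> np.ndarray:
    """Fold assignment (0..k-1 per sample), stratified by class."""
    fold = np.empty(len(y), dtype=int)
    _, idx1, idx2 = class_indices(y)
    for idx in (idx1, idx2):
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % k_folds
    return fold


# ---------------------------------------------------------------------------
# Fast inner-CV machinery
# ---------------------------------------------------------------------------

class _ClassStats:
    """Sufficient statistics (sums and Gram matrices) per class, supporting
    cheap leave-fold-out recombination."""

    def __init__(self, X: np.ndarray, idx: np.ndarray):
        self.X = X[idx]
        self.n = idx.size
        self.sum = self.X.sum(axis=0)
        self.gram = self.X.T @ self.X

    def minus(self, mask_rows: np.ndarray):
        """Stats after removing the given rows (boolean mask into self.X)."""
        Xf = self.X[mask_rows]
        n = self.n - Xf.shape[0]
        s = self.sum - Xf.sum(axis=0)
        gram = self.gram - Xf.T @ Xf
        mu = s / n
        scatter = gram - np.outer(mu, s)  # sum (x-mu)(x-mu)'
        return n, mu, scatter


def _score_gaussian_pair(Xte, mu1, mu2, log_pi1, log_pi2, cho1, cho2,
                         logdet1, logdet2) -> np.ndarray:
    q = []
    for mu, cho in ((mu1, cho1), (mu2, cho2)):
        z = linalg.solve_triangular(cho[0], (Xte - mu).T, lower=True)
        q.append(np.sum(z * z, axis=0))
    return (log_pi1 - 0.5 * logdet1 - 0.5 * q[0]) - (
        log_pi2 - 0.5 * logdet2 - 0.5 * q[1]
    )


def _grid_accuracy(Xtr, ytr, targets, spec, flavor, k_folds, rng):
    """Mean inner-fold accuracy for every (lam, eps) grid point.

    ``targets[k]`` maps eps -> target matrix for class k (shared for the
    linear flavor).  Returns a dict {(lam, eps): mean accuracy}; grid points
    whose covariance cannot be factorized (lam = 1 with n <= p) get -inf.
    """
    classes, idx1, idx2 = class_indices(ytr)
    n_min = min(idx1.size, idx2.size)
    if k_folds > n_min:
        logger.warning("reducing inner folds from %d to %d (smallest class)",
                       k_folds, n_min)
        k_folds = n_min
    fold = _stratified_folds(ytr, k_folds, rng)
    stats1 = _ClassStats(Xtr, idx1)
    stats2 = _ClassStats(Xtr, idx2)
    acc = {}
    hits = {key: 0.0 for key in _grid_points(spec)}
    total = 0
    for f in range(k_folds):
        te_mask = fold == f
        Xte = Xtr[te_mask]
        yte = ytr[te_mask]
        if Xte.shape[0] == 0:
            continue
        n1, mu1, sc1 = stats1.minus(fold[idx1] == f)
        n2, mu2, sc2 = stats2.minus(fold[idx2] == f)
        if n1 < 2 or n2 < 2:
            continue
        total += Xte.shape[0]
        n_train = n1 + n2
        log_pi1, log_pi2 = np.log(n1 / n_train), np.log(n2 / n_train)
        truth_is_1 = yte == classes[0]
        if flavor == "linear":
            S1 = S2 = (sc1 + sc2) / (n_train - 2)
        else:
            S1, S2 = sc1 / (n1 - 1), sc2 / (n2 - 1)
        for eps in spec.eps_grid:
            T1 = targets[0][eps]
            T2 = targets[-1][eps]
            for lam in spec.lam_grid:
                sig1 = lam * S1 + (1.0 - lam) * T1
                try:
                    cho1 = linalg.cho_factor(sig1, lower=True)
                    if flavor == "linear":
                        cho2 = cho1
                    else:
                        cho2 = linalg.cho_factor(
                            lam * S2 + (1.0 - lam) * T2, lower=True)
                except linalg.LinAlgError:
                    hits[(lam, eps)] = -np.inf
                    continue
                ld1 = 2.0 * np.sum(np.log(np.diag(cho1[0])))
                ld2 = ld1 if cho2 is cho1 else 2.0 * np.sum(np.log(np.diag(cho2[0])))
                f_scores = _score_gaussian_pair(
                    Xte, mu1, mu2, log_pi1, log_pi2, cho1, cho2, ld1, ld2)
                hits[(lam, eps)] += np.sum((f_scores > 0) == truth_is_1)
    for key, h in hits.items():
        acc[key] = h / total if np.isfinite(h) else -np.inf
    return acc


def _grid_points(spec: ShrinkageSpec):
    # Sorted so that ties resolve to the smallest lam, then the smallest eps.
    return [(lam, eps) for lam in sorted(spec.lam_grid) for eps in sorted(spec.eps_grid)]


def select_hyperparameters(
    X_train, y_train, graphs, spec: ShrinkageSpec | None = None,
    flavor: str = "linear", k_folds: int = 10, seed=0,
) -> tuple[float, float]:
    """Inner k-fold grid search for (lam, eps), maximizing mean accuracy.

    Ties prefer the smallest ``lam`` then the smallest ``eps`` (the
    graph-dominated corner of the grid).  Deterministic under a fixed seed.
    """
    spec = spec or ShrinkageSpec()
    rng = np.random.default_rng(seed)
    glist = [graphs] if isinstance(graphs, Graph) else list(graphs)
    targets = [
        {eps: shrinkage_target(laplacian(g), eps).matrix for eps in spec.eps_grid}
        for g in glist
    ]
    acc = _grid_accuracy(np.asarray(X_train, float), np.asarray(y_train),
                         targets, spec, flavor, k_folds, rng)
    best = None
    best_acc = -np.inf
    for key in _grid_points(spec):
        if acc[key] > best_acc:
            best, best_acc = key, acc[key]
    if best is None or not np.isfinite(best_acc):
        raise RuntimeError("no hyperparameter grid point could be evaluated")
    return best


# ---------------------------------------------------------------------------
# Outer MCCV
# ---------------------------------------------------------------------------

def mccv(
    X, y, fit_predict, n_iter: int = 100, train_frac: float = 2.0 / 3.0,
    seed=0, method_id: str = "", setting_id: str = "",
) -> PerformanceSummary:
    """Monte Carlo cross-validation of a classifier.

    ``fit_predict(X_train, y_train, X_test, rng)`` must return
    ``(y_pred, selected)`` where ``selected`` (hyperparameter record or
    ``None``) is bookkeeping only.  Test labels are never passed in, so a
    classifier cannot leak held-out information by construction.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rates, selections = [], []
    for it in range(n_iter):
        rng = np.random.default_rng([_seed_int(seed), it])
        tr, te = _stratified_split(y, train_frac, rng)
        y_pred, selected = fit_predict(X[tr], y[tr], X[te], rng)
        rates.append(100.0 * float(np.mean(np.asarray(y_pred) == y[te])))
        selections.append(selected)
    return PerformanceSummary(rates, method_id=method_id, setting_id=setting_id,
                              selected_hyperparams=selections)


def _seed_int(seed) -> int:
    return int(seed) % (2**31)


def make_gcda_fit_predict(
    graphs, spec: ShrinkageSpec | None = None, flavor: str = "linear",
    select: bool = True, k_folds: int = 10,
):
    """gCDA under the :func:`mccv` contract.

    With ``select=True`` (default) each training fold re-runs the inner
    grid search; the selected ``(lam, eps)`` pair is recorded per iteration.
    """
    spec = spec or ShrinkageSpec()

    def fit_predict(Xtr, ytr, Xte, rng):
        if select:
            lam, eps = select_hyperparameters(
                Xtr, ytr, graphs, spec, flavor=flavor, k_folds=k_folds,
                seed=rng.integers(2**31),
            )
            used = ShrinkageSpec(lam=lam, eps=eps, lam_grid=spec.lam_grid,
                                 eps_grid=spec.eps_grid)
        else:
            used = spec
        model = clf.fit(Xtr, ytr, graphs, used, flavor=flavor)
        return clf.predict(model, Xte), (used.lam, used.eps)

    return fit_predict


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

def degradation_experiment(
    config: SimulationConfig, ladder=None, n_iter: int = 20,
    spec: ShrinkageSpec | None = None, select: bool = True, seed=0,
) -> list[tuple[int, PerformanceSummary]]:
    """Classification performance along a graph-misspecification ladder.

    One dataset is simulated from ``config``; for each ladder graph, gCDA
    integrating that graph is evaluated by MCCV on that same dataset.
    ``ladder`` is either a list of ``(Graph, achieved_distance)`` pairs (as
    produced by :func:`~gcda.simulation.misspecification_ladder`) or a list
    of rewiring-move counts.  Rows are sorted by achieved distance.
    """
    X, y, _ = simulate(config)
    if ladder is None:
        ladder = [0, config.p // 4, config.p // 2, config.p]
    if ladder and not isinstance(ladder[0], tuple):
        ladder = misspecification_ladder(config, list(ladder))
    rows = []
    for g, dist in ladder:
        fp = make_gcda_fit_predict(g, spec, flavor="linear", select=select)
        summary = mccv(X, y, fp, n_iter=n_iter, seed=seed,
                       method_id="gcda", setting_id=f"distance={dist}")
        rows.append((dist, summary))
    rows.sort(key=lambda r: r[0])
    return rows
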