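"""Graph-constrained discriminant analysis (gCDA).

A binary Gaussian classifier whose within-class covariance estimate is
shrunk toward a gene-network target (see :mod:`gcda.covariance`).  The
decision rule is the Bayes discriminant

    f(x) = log[ pi_1 phi(x; mu_1, Sigma_1) ] - log[ pi_2 phi(x; mu_2, Sigma_2) ]

with ``f(x) > 0`` assigning class 1 and ``f(x) <= 0`` class 2 (ties broken
to class 2).  Two flavors:

* linear — one shared covariance ``Sigma = lam * S_W + (1-lam) * T(G)`` from
  the pooled within-class scatter and a single network; the score is affine
  in x with Fisher direction ``w = Sigma^{-1} (mu_1 - mu_2)``.
* quadratic — one covariance (and one network) per class,
  ``Sigma_k = lam * S_k + (1-lam) * T(G_k)``; the score is quadratic in x
  and carries log-determinant terms.

All solves and log-determinants go through Cholesky factorizations; no
explicit inverse is formed unless :func:`fisher_axis` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .covariance import (
    ShrinkageSpec,
    class_indices,
    empirical_covariance,
    pooled_within_covariance,
    shrink,
    shrinkage_target,
)
from .graphs import Graph, laplacian

__all__ = ["GcdaModel", "fit", "discriminant_score", "scores", "predict", "fisher_axis"]


@dataclass
class GcdaModel:
    """Fitted gCDA model (see module docstring for the decision rule)."""

    flavor: str
    classes: tuple
    mu1: np.ndarray
    mu2: np.ndarray
    pi1: float
    pi2: float
    sigma1: np.ndarray
    sigma2: np.ndarray
    lam: float
    eps: float
    graph_ids: tuple[str, ...] = ("graph",)
    # Cholesky caches, built once at assembly.
    _cho1: tuple = field(default=None, repr=False)
    _cho2: tuple = field(default=None, repr=False)
    logdet1: float = field(default=np.nan)
    logdet2: float = field(default=np.nan)

    @property
    def p(self) -> int:
        return self.mu1.shape[0]

    def save(self, path) -> None:
        """Serialize to a structured YAML text file for audit/reload."""
        import yaml

        payload = {
            "format": "gcda-model-v1",
            "flavor": self.flavor,
            "classes": [_plain(c) for c in self.classes],
            "pi1": float(self.pi1),
            "pi2": float(self.pi2),
            "lam": float(self.lam),
            "eps": float(self.eps),
            "graph_ids": list(self.graph_ids),
            "mu1": self.mu1.tolist(),
            "mu2": self.mu2.tolist(),
            "sigma1": self.sigma1.tolist(),
            "sigma2": self.sigma2.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GcdaModel":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("format") != "gcda-model-v1":
            raise ValueError(f"not a gcda model file: {path}")
        return _assemble(
            flavor=d["flavor"],
            classes=tuple(d["classes"]),
            mu1=np.asarray(d["mu1"], float),
            mu2=np.asarray(d["mu2"], float),
            pi1=d["pi1"],
            pi2=d["pi2"],
            sigma1=np.asarray(d["sigma1"], float),
            sigma2=np.asarray(d["sigma2"], float),
            lam=d["lam"],
            eps=d["eps"],
            graph_ids=tuple(d["graph_ids"]),
        )


def _plain(value):
    return value.item() if isinstance(value, np.generic) else value


def _chol_or_advise(sigma: np.ndarray, lam: float):
    try:
        return linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "shrunk covariance is not positive definite; with lam = 1 and "
            "n <= p the empirical estimate is singular — use lam < 1 to "
            "shrink toward the graph target"
        ) from err


def _assemble(flavor, classes, mu1, mu2, pi1, pi2, sigma1, sigma2, lam, eps,
              graph_ids) -> GcdaModel:
    model = GcdaModel(
        flavor=flavor, classes=tuple(classes),
        mu1=np.asarray(mu1, float), mu2=np.asarray(mu2, float),
        pi1=float(pi1), pi2=float(pi2),
        sigma1=np.asarray(sigma1, float), sigma2=np.asarray(sigma2, float),
        lam=float(lam), eps=float(eps), graph_ids=tuple(graph_ids),
    )
    model._cho1 = _chol_or_advise(model.sigma1, lam)
    if flavor == "linear" and sigma2 is sigma1:
        model._cho2 = model._cho1
    else:
        model._cho2 = _chol_or_advise(model.sigma2, lam)
    model.logdet1 = 2.0 * np.sum(np.log(np.diag(model._cho1[0])))
    model.logdet2 = 2.0 * np.sum(np.log(np.diag(model._cho2[0])))
    return model


def fit(
    X: np.ndarray,
    y: np.ndarray,
    graphs: Graph | tuple[Graph, ...],
    spec: ShrinkageSpec | None = None,
    flavor: str = "linear",
    uniform_priors: bool = False,
) -> GcdaModel:
    """Fit a linear or quadratic gCDA model.

    Parameters
    ----------
    X, y
        ``n x p`` data and binary labels (any two distinct values; mapped to
        class 1/2 by sorted order).
    graphs
        One graph (linear) or two graphs, one per class (quadratic).
    spec
        Shrinkage hyperparameters; ``spec.lam`` and ``spec.eps`` are used as
        given (cross-validated selection lives in :mod:`gcda.evaluation`).
    uniform_priors
        Use ``pi_1 = pi_2 = 1/2`` instead of class frequencies.
    """
    spec = spec or ShrinkageSpec()
    X = np.asarray(X, dtype=float)
    if flavor not in ("linear", "quadratic"):
        raise ValueError(f"flavor must be 'linear' or 'quadratic', got {flavor!r}")
    glist = [graphs] if isinstance(graphs, Graph) else list(graphs)
    if flavor == "linear" and len(glist) != 1:
        raise ValueError(f"linear gCDA takes exactly one graph, got {len(glist)}")
    if flavor == "quadratic" and len(glist) != 2:
        raise ValueError(f"quadratic gCDA takes exactly two graphs, got {len(glist)}")
    for g in glist:
        if g.n_vertices != X.shape[1]:
            raise ValueError(
                f"graph has {g.n_vertices} vertices but data has {X.shape[1]} columns"
            )

    classes, idx1, idx2 = class_indices(y)
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError(
            f"each class needs >= 2 samples, got sizes {idx1.size} and {idx2.size}"
        )
    mu1 = X[idx1].mean(axis=0)
    mu2 = X[idx2].mean(axis=0)
    n = X.shape[0]
    pi1, pi2 = (0.5, 0.5) if uniform_priors else (idx1.size / n, idx2.size / n)

    targets = [shrinkage_target(laplacian(g), spec.eps).matrix for g in glist]
    if flavor == "linear":
        S = pooled_within_covariance(X, y)
        sigma1 = sigma2 = shrink(S.matrix, targets[0], spec.lam).matrix
    else:
        S1 = empirical_covariance(X[idx1]).matrix
        S2 = empirical_covariance(X[idx2]).matrix
        sigma1 = shrink(S1, targets[0], spec.lam).matrix
        sigma2 = shrink(S2, targets[1], spec.lam).matrix
    graph_ids = tuple(f"graph{k + 1}:{g.n_edges} edges" for k, g in enumerate(glist))
    return _assemble(flavor, classes, mu1, mu2, pi1, pi2, sigma1, sigma2,
                     spec.lam, spec.eps, graph_ids)


def scores(model: GcdaModel, X: np.ndarray) -> np.ndarray:
    """Vector of discriminant scores for the rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.p:
        raise ValueError(f"expected {model.p} columns, got {X.shape[1]}")
    if model._cho1 is None:
        raise ValueError("model is not fitted")
    q = []
    for mu, cho in ((model.mu1, model._cho1), (model.mu2, model._cho2)):
        D = X - mu
        z = linalg.solve_triangular(cho[0], D.T, lower=True)
        q.append(np.sum(z * z, axis=0))
    return (
        (np.log(model.pi1) - 0.5 * model.logdet1 - 0.5 * q[0])
        - (np.log(model.pi2) - 0.5 * model.logdet2 - 0.5 * q[1])
    )


def discriminant_score(model: GcdaModel, x: np.ndarray) -> float:
    """Bayes discriminant score f(x); positive means class 1."""
    return float(scores(model, np.asarray(x, float).reshape(1, -1))[0])


def predict(model: GcdaModel, X: np.ndarray) -> np.ndarray:
    """Class labels (in the caller's encoding) for the rows of X.

    ``f(x) > 0`` gives class 1; ties at 0 go to class 2.
    """
    f = scores(model, X)
    out = np.where(f > 0, model.classes[0], model.classes[1])
    return out


def fisher_axis(model: GcdaModel) -> np.ndarray:
    """Unit-length discriminant axis ``w ∝ Sigma^{-1}(mu_1 - mu_2)``.

    Defined for the linear flavor only: with a shared covariance the Fisher
    ratio maximizer and the Bayes rule share this direction.
    """
    if model.flavor != "linear":
        raise ValueError("fisher_axis is defined for the linear flavor only")
    w = linalg.cho_solve(model._cho1, model.mu1 - model.mu2)
    return w / np.linalg.norm(w)
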