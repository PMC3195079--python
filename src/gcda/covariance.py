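"""Covariance estimation with a Gaussian-graphical-model shrinkage target.

In the high-dimensional setting (p comparable to or exceeding n) the
empirical covariance matrix is singular and discriminant analysis needs a
regularized estimate.  Here the regularizer encodes a gene network G through
its Laplacian L: the target

    T(G, eps) = (L + eps * I)^{-1}

is the covariance of a Gaussian graphical model whose precision matrix
``L + eps*I`` has a zero at (i, j), i != j, exactly when (i, j) is not an
edge of G — the conditional-independence pattern of the GGM.  ``eps > 0``
conditions the target (L alone is singular: the constant vector is in its
nullspace).

The estimate entered into the classifier is the convex shrinkage

    Sigma_hat = lam * S + (1 - lam) * T,    lam in [0, 1],

with S the empirical (pooled within-class or per-class) covariance.  ``lam``
near 0 means the graph dominates.  No trace or diagonal rescaling of T is
applied before shrinking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "ShrinkageSpec",
    "CovarianceEstimate",
    "shrinkage_target",
    "empirical_covariance",
    "pooled_within_covariance",
    "shrink",
]

DEFAULT_LAM_GRID = tuple(np.round(np.linspace(0.0, 1.0, 21), 2))
DEFAULT_EPS_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class ShrinkageSpec:
    """Shrinkage hyperparameters and their cross-validation grids.

    ``lam`` is the weight on the empirical covariance (0 = pure graph target,
    1 = pure empirical); ``eps`` conditions the target ``(L + eps*I)^{-1}``.
    """

    lam: float = 0.05
    eps: float = 1.0
    lam_grid: tuple[float, ...] = DEFAULT_LAM_GRID
    eps_grid: tuple[float, ...] = DEFAULT_EPS_GRID

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.eps <= 0.0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if len(self.lam_grid) == 0 or len(self.eps_grid) == 0:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(not 0.0 <= l <= 1.0 for l in self.lam_grid):
            raise ValueError("lam_grid values must be in [0, 1]")
        if any(e <= 0.0 for e in self.eps_grid):
            raise ValueError("eps_grid values must be positive")


@dataclass
class CovarianceEstimate:
    """A symmetric p x p covariance estimate with provenance.

    ``kind`` is one of ``empirical``, ``target``, ``shrunk``; ``class_id``
    is 1, 2 or ``"pooled"`` where relevant.
    """

    matrix: np.ndarray
    kind: str
    class_id: object = None

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"covariance must be square, got shape {M.shape}")
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        if self.kind not in ("empirical", "target", "shrunk"):
            raise ValueError(f"unknown kind {self.kind!r}")
        self.matrix = (M + M.T) / 2.0

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


def shrinkage_target(L: np.ndarray, eps: float) -> CovarianceEstimate:
    """GGM shrinkage target ``T = (L + eps*I)^{-1}`` from a graph Laplacian.

    T is symmetric positive definite and its inverse carries the graph's
    conditional-independence zero pattern: ``(T^{-1})_{ij} = 0`` for i != j
    exactly off the edge set.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError(f"Laplacian must be square, got shape {L.shape}")
    if not np.allclose(L, L.T, atol=1e-10):
        raise ValueError("Laplacian must be symmetric")
    if eps <= 0.0:
        raise ValueError(f"eps must be positive, got {eps}")
    p = L.shape[0]
    prec = L + eps * np.eye(p)
    try:
        c, low = linalg.cho_factor(prec)
    except linalg.LinAlgError as err:  # pragma: no cover - L PSD + eps>0 is PD
        raise linalg.LinAlgError(
            "L + eps*I is not positive definite; is L a valid Laplacian?"
        ) from err
    T = linalg.cho_solve((c, low), np.eye(p))
    return CovarianceEstimate((T + T.T) / 2.0, kind="target")


def empirical_covariance(X: np.ndarray, ddof: int = 1) -> CovarianceEstimate:
    """Empirical covariance of the rows of X, centered at the sample mean.

    Default divisor ``n - 1`` (unbiased).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    S = np.cov(X, rowvar=False, ddof=ddof)
    S = np.atleast_2d(S)
    return CovarianceEstimate(S, kind="empirical")


def class_indices(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a binary label vector into (classes, idx1, idx2).

    Classes are the two distinct label values in sorted order; class 1 is the
    smaller.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"expected exactly 2 classes, got {classes.size}: {classes.tolist()}"
        )
    return classes, np.flatnonzero(y == classes[0]), np.flatnonzero(y == classes[1])


def pooled_within_covariance(
    X: np.ndarray, y: np.ndarray, ddof: int = 2
) -> CovarianceEstimate:
    """Pooled within-class covariance: summed per-class centered scatter over
    ``n - ddof`` (default ``n - 2``, two estimated class means)."""
    X = np.asarray(X, dtype=float)
    _, idx1, idx2 = class_indices(y)
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError(
            f"each class needs >= 2 samples, got sizes {idx1.size} and {idx2.size}"
        )
    n = X.shape[0]
    scatter = np.zeros((X.shape[1], X.shape[1]))
    for idx in (idx1, idx2):
        Xc = X[idx] - X[idx].mean(axis=0)
        scatter += Xc.T @ Xc
    S = scatter / (n - ddof)
    return CovarianceEstimate((S + S.T) / 2.0, kind="empirical", class_id="pooled")


def shrink(
    S: CovarianceEstimate | np.ndarray,
    T: CovarianceEstimate | np.ndarray,
    lam: float,
) -> CovarianceEstimate:
    """Convex combination ``lam * S + (1 - lam) * T``.

    Positive definite whenever ``lam < 1`` (T is PD by construction).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    Sm = S.matrix if isinstance(S, CovarianceEstimate) else np.asarray(S, float)
    Tm = T.matrix if isinstance(T, CovarianceEstimate) else np.asarray(T, float)
    if Sm.shape != Tm.shape:
        raise ValueError(f"dimension mismatch: {Sm.shape} vs {Tm.shape}")
    class_id = S.class_id if isinstance(S, CovarianceEstimate) else None
    return CovarianceEstimate(lam * Sm + (1.0 - lam) * Tm, kind="shrunk", class_id=class_id)


def write_covariance(est: CovarianceEstimate, path, labels=None, sep: str = "\t") -> None:
    """Write a covariance matrix as delimited text with gene-label headers."""
    import pandas as pd

    p = est.p
    labels = list(labels) if labels is not None else [f"v{i}" for i in range(p)]
    pd.DataFrame(est.matrix, index=labels, columns=labels).to_csv(path, sep=sep)
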