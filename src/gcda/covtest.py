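"""High-dimensional two-sample test of covariance equality.

Decides between linear gCDA (shared covariance) and quadratic gCDA (one
covariance per class) by testing H0: Sigma_1 = Sigma_2 in the regime where
the number of variables p is of the same order as the sample sizes, where
the classical likelihood-ratio (Box) test breaks down.

The statistic is of the trace form used by high-dimensional covariance
tests: with sample covariances S_k (divisor n_k = N_k - 1) it targets
``tr((Sigma_1 - Sigma_2)^2)`` through

    t = a_1 + a_2 - 2 tr(S_1 S_2),

where ``a_k = n_k^2 / ((n_k - 1)(n_k + 2)) * [tr(S_k^2) - tr(S_k)^2 / n_k]``
is the standard unbiased estimator of ``tr(Sigma_k^2)`` under normality and
``tr(S_1 S_2)`` is unbiased for ``tr(Sigma_1 Sigma_2)`` by independence, so
``E[t] = 0`` under H0.  Under H0 the asymptotic (n, p growing together)
standard deviation of t is

    sd = 2 * (1/n_1 + 1/n_2) * tr(Sigma^2),

estimated by plugging the pooled-covariance unbiased estimator of
``tr(Sigma^2)`` into the same formula; ``z = t / sd`` is referred to the
standard normal, two-sided.  The calibration of this standardization
(z ~ N(0, 1) under H0) is exercised directly by the test suite via
Kolmogorov–Smirnov and type-I-error simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CovEqualityResult", "schott_test"]


@dataclass(frozen=True)
class CovEqualityResult:
    """Outcome of the covariance-equality test.

    ``statistic`` is the standardized trace statistic (asymptotically
    standard normal under H0); ``recommended_flavor`` is ``"quadratic"``
    when H0 is rejected at ``decision_at`` and ``"linear"`` otherwise.
    """

    statistic: float
    p_value: float
    n1: int
    n2: int
    p: int
    decision_at: float = 0.05

    @property
    def reject(self) -> bool:
        return self.p_value < self.decision_at

    @property
    def recommended_flavor(self) -> str:
        return "quadratic" if self.reject else "linear"


def _unbiased_tr_sigma2(S: np.ndarray, n: int) -> float:
    """Unbiased estimator of tr(Sigma^2) from a sample covariance with n
    degrees of freedom (divisor n), under normality."""
    tr_S2 = float(np.einsum("ij,ji->", S, S))
    tr_S = float(np.trace(S))
    return n**2 / ((n - 1) * (n + 2)) * (tr_S2 - tr_S**2 / n)


def schott_test(
    X1: np.ndarray, X2: np.ndarray, decision_at: float = 0.05
) -> CovEqualityResult:
    """Two-sample high-dimensional test of H0: Sigma_1 = Sigma_2.

    Parameters
    ----------
    X1, X2
        Samples as ``N_k x p`` matrices (rows are observations); both need
        ``N_k >= 4`` and the same p.  The statistic is symmetric in the two
        samples and invariant to a common orthogonal rotation.
    decision_at
        Significance level for the linear-vs-quadratic recommendation.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.ndim != 2 or X2.ndim != 2:
        raise ValueError("samples must be 2-d arrays (observations x variables)")
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(f"variable counts differ: {X1.shape[1]} != {X2.shape[1]}")
    N1, p = X1.shape
    N2 = X2.shape[0]
    if N1 < 4 or N2 < 4:
        raise ValueError(
            f"each sample needs >= 4 observations, got {N1} and {N2}"
        )
    n1, n2 = N1 - 1, N2 - 1
    S1 = np.cov(X1, rowvar=False)
    S2 = np.cov(X2, rowvar=False)
    S1 = np.atleast_2d(S1)
    S2 = np.atleast_2d(S2)

    t = (
        _unbiased_tr_sigma2(S1, n1)
        + _unbiased_tr_sigma2(S2, n2)
        - 2.0 * float(np.einsum("ij,ji->", S1, S2))
    )
    n = n1 + n2
    S_pool = (n1 * S1 + n2 * S2) / n
    a_pool = _unbiased_tr_sigma2(S_pool, n)
    sd = 2.0 * (1.0 / n1 + 1.0 / n2) * a_pool
    z = t / sd
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return CovEqualityResult(
        statistic=float(z), p_value=p_value, n1=N1, n2=N2, p=p,
        decision_at=decision_at,
    )
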