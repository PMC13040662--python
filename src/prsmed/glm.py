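"""Logistic regression by iteratively reweighted least squares.

A small, fast Newton/IRLS fitter is used throughout the package instead of a
general GLM framework because the bootstrap loops refit the same designs
thousands of times and benefit from warm starts and minimal overhead.
Correctness is cross-checked against an independent implementation in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError

_ETA_CLIP = 35.0  # |linear predictor| beyond this saturates the likelihood


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit.

    Attributes
    ----------
    params : coefficient vector (intercept first)
    names : term names aligned with params
    llf : maximized log-likelihood (<= 0)
    fitted : fitted probabilities in (0, 1)
    n : number of observations
    converged : False under separation or iteration exhaustion; downstream
        consumers must check this flag before trusting the coefficients.
    cov : inverse observed information (Wald covariance), or None if the
        information matrix was singular at the optimum.
    """

    params: np.ndarray
    names: list = field(default_factory=list)
    llf: float = np.nan
    fitted: np.ndarray = None
    n: int = 0
    converged: bool = False
    cov: np.ndarray = None

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        j = self.names.index(name)
        return float(np.sqrt(self.cov[j, j])) if self.cov is not None else np.nan


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


def log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    names: list | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    beta0: np.ndarray | None = None,
    check_rank: bool = True,
) -> LogisticFit:
    """Fit P(y=1) = logit^-1(X beta) by Newton-Raphson IRLS.

    Convergence: max absolute coefficient change < ``tol``, within
    ``max_iter`` iterations.  Separation or a singular weighted information
    matrix yields a fit with ``converged=False`` rather than an exception;
    a rank-deficient design raises :class:`DesignError`.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y and X have incompatible shapes")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if check_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")

    k = X.shape[1]
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    converged = False
    singular = False
    for _ in range(max_iter):
        eta = X @ beta
        p = _sigmoid(eta)
        w = p * (1 - p)
        grad = X.T @ (y - p)
        XtWX = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        beta += step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    p = _sigmoid(X @ beta)
    llf = log_likelihood(y, p)
    cov = None
    if not singular:
        w = p * (1 - p)
        XtWX = (X * w[:, None]).T @ X
        try:
            cov = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            cov = None
    # runaway coefficients indicate separation even if the last step was small
    if np.max(np.abs(beta)) > 1e3:
        converged = False
    return LogisticFit(
        params=beta,
        names=list(names) if names is not None else [f"x{j}" for j in range(k)],
        llf=llf,
        fitted=p,
        n=y.size,
        converged=converged,
        cov=cov,
    )


def fit_intercept_only(y: np.ndarray) -> LogisticFit:
    """Closed-form intercept-only fit: beta0 = logit(mean(y))."""
    y = np.asarray(y, dtype=float)
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        raise ValueError("outcome has a single class")
    beta = np.array([np.log(pbar / (1 - pbar))])
    p = np.full(y.size, pbar)
    return LogisticFit(
        params=beta, names=["intercept"], llf=log_likelihood(y, p),
        fitted=p, n=y.size, converged=True,
        cov=np.array([[1.0 / (y.size * pbar * (1 - pbar))]]),
    )


def fit_linear(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS coefficients by least squares (used for mediator models where
    only the point estimate is needed)."""
    beta, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
    return beta
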