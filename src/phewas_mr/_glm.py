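"""Fast logistic-regression fitting used by the per-variant scans.

A thin iteratively-reweighted-least-squares (IRLS) Newton solver tuned for
the pattern the association scans need: one fixed covariate block and
thousands of single-column perturbations (one per variant or per phecode).
Wald standard errors come from the inverse observed information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_ITER = 100
TOL = 1e-8
# |linear predictor| beyond which the fit is treated as (quasi-)separated
ETA_CAP = 30.0


@dataclass
class LogisticFit:
    """Result of one logistic fit.

    beta/se are aligned with the design-matrix columns; ``converged`` is
    False for separated or non-converged fits, in which case downstream
    code flags the record rather than failing.
    """

    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int
    loglik: float

    def wald_z(self) -> np.ndarray:
        return self.beta / self.se

    def cov(self) -> np.ndarray:  # pragma: no cover - convenience only
        raise NotImplementedError


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    start: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> LogisticFit:
    """Fit logit(P(y=1)) = X beta (+ offset) by IRLS.

    X must already contain an intercept column if one is wanted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = 0.0
    if start is None:
        beta = np.zeros(p)
        # intercept warm start at the empirical log-odds when col 0 is 1s
        ybar = np.clip(y.mean(), 1e-10, 1 - 1e-10)
        if np.all(X[:, 0] == 1.0):
            beta[0] = np.log(ybar / (1 - ybar))
    else:
        beta = np.array(start, dtype=float)

    converged = False
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta + offset
        eta = np.clip(eta, -ETA_CAP, ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # Fisher scoring step: (X'WX) d = X'(y - mu)
        Xw = X * w[:, None]
        H = X.T @ Xw
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return LogisticFit(beta, np.full(p, np.nan), False, it, -np.inf)
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if np.max(np.abs(step)) < tol or abs(ll - ll_old) < tol * (abs(ll) + tol):
            converged = True
            break
        ll_old = ll

    eta = np.clip(X @ beta + offset, -ETA_CAP, ETA_CAP)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    # quasi-separation: exploding coefficients or SEs
    if converged and (np.any(~np.isfinite(se)) or np.any(np.abs(beta) > ETA_CAP)):
        converged = False
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return LogisticFit(beta, se, converged, it, ll)


def add_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    """Prepend a column of ones; X may be None (intercept-only design)."""
    ones = np.ones((n, 1))
    if X is None or (hasattr(X, "size") and X.size == 0):
        return ones
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.hstack([ones, X])
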