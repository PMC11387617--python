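"""Elastic-net coordinate descent and regularization paths for the student.

The student is an ordinary penalized linear regression of teacher-predicted
linear predictors on the raw features:

    min_{b0, beta}  (1/(2n)) ||y - b0 - X beta||^2
                    + lambda * ( alpha ||beta||_1 + (1-alpha)/2 ||beta||_2^2 )

solved by cyclic coordinate descent with soft-thresholding on internally
standardized features (Gram/covariance updates, numba-jitted), warm-started
along a geometric grid of L lambdas from lambda_max (the smallest penalty
with an all-zero solution) down to eps * lambda_max.  Coefficients are
returned on the original feature scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["lambda_path", "elastic_net_cd", "fit_path", "RegularizationPathFit"]


@njit(cache=True)
def _cd_gram(G, c, lam_l1, lam_l2, beta, tol, max_iter):
    """Cyclic coordinate descent on the standardized-scale normal equations.

    G = Xs'Xs/n, c = Xs'yc/n.  Returns the number of full sweeps used.
    """
    p = beta.shape[0]
    for it in range(max_iter):
        dmax = 0.0
        for j in range(p):
            gj = 0.0
            for k in range(p):
                gj += G[j, k] * beta[k]
            rho = c[j] - gj + G[j, j] * beta[j]
            denom = G[j, j] + lam_l2
            if denom <= 0.0:
                bnew = 0.0
            elif rho > lam_l1:
                bnew = (rho - lam_l1) / denom
            elif rho < -lam_l1:
                bnew = (rho + lam_l1) / denom
            else:
                bnew = 0.0
            d = abs(bnew - beta[j])
            if d > dmax:
                dmax = d
            beta[j] = bnew
        if dmax < tol:
            return it + 1
    return max_iter


class _Standardized:
    """Feature standardization + response centering shared across a path."""

    def __init__(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")
        if y.shape != (X.shape[0],):
            raise ValueError("y must align with the rows of X")
        self.n, self.p = X.shape
        self.x_mean = X.mean(axis=0)
        self.x_scale = X.std(axis=0)
        self.x_scale = np.where(self.x_scale == 0, 1.0, self.x_scale)
        self.y_mean = float(y.mean())
        self.Xs = (X - self.x_mean) / self.x_scale
        self.yc = y - self.y_mean
        self.G = (self.Xs.T @ self.Xs) / self.n
        self.c = (self.Xs.T @ self.yc) / self.n

    def unstandardize(self, beta_std):
        beta = beta_std / self.x_scale
        intercept = self.y_mean - float(self.x_mean @ beta)
        return beta, intercept

    def kkt_violation(self, beta_std, lam, alpha):
        """Max violation of the stationarity conditions at a solution."""
        grad = self.c - self.G @ beta_std  # (1/n) Xs'(residual)
        active = beta_std != 0
        v_inactive = np.max(
            np.clip(np.abs(grad[~active]) - lam * alpha, 0, None), initial=0.0
        )
        v_active = np.max(
            np.abs(grad[active] - lam * alpha * np.sign(beta_std[active])
                   - lam * (1 - alpha) * beta_std[active]),
            initial=0.0,
        )
        return max(float(v_inactive), float(v_active))


def lambda_path(X, y, alpha: float = 0.9, L: int = 100, eps: float | None = None):
    """Geometric grid of L penalties from lambda_max down to eps*lambda_max.

    lambda_max = max_j |<x_j, y - ybar>| / (n * alpha) on internally
    standardized features: the smallest penalty whose elastic-net solution
    is identically zero (path index 0 in the reported fits).  Default
    eps is 0.01 when n > p and 0.05 otherwise.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if L < 2:
        raise ValueError("L must be >= 2")
    std = _Standardized(X, y)
    if np.allclose(std.yc, 0):
        raise ValueError("teacher predictions are constant; nothing to distill")
    lam_max = float(np.max(np.abs(std.c))) / alpha
    if lam_max <= 0:
        raise ValueError("teacher predictions are orthogonal to every feature")
    if eps is None:
        eps = 0.01 if std.n > std.p else 0.05
    return np.geomspace(lam_max, eps * lam_max, int(L))


def elastic_net_cd(
    X, y, lam: float, alpha: float = 0.9, init=None,
    tol: float = 1e-7, max_iter: int = 100_000,
):
    """Single elastic-net solve; returns (beta, intercept) on the original
    feature scale.  ``init`` warm-starts on the standardized scale divided
    out internally (pass raw-scale coefficients)."""
    std = _Standardized(X, y)
    beta_std = (
        np.zeros(std.p) if init is None
        else np.asarray(init, dtype=float) * std.x_scale
    )
    sweeps = _cd_gram(std.G, std.c, lam * alpha, lam * (1 - alpha),
                      beta_std, tol, max_iter)
    if sweeps >= max_iter:
        warnings.warn(
            f"coordinate descent hit max_iter={max_iter} sweeps", UserWarning,
            stacklevel=2,
        )
    beta, intercept = std.unstandardize(beta_std)
    return beta, intercept


@dataclass
class RegularizationPathFit:
    """Elastic-net solutions along a decreasing lambda grid.

    ``coefs[l]`` are original-scale coefficients at ``lambdas[l]``;
    ``n_nonzero[l]`` the active-set size; index 0 is the fully sparse head
    of the path.
    """

    lambdas: np.ndarray
    alpha: float
    coefs: np.ndarray        # (L, p)
    intercepts: np.ndarray   # (L,)
    n_nonzero: np.ndarray    # (L,)
    kkt_max_violation: float = 0.0

    @property
    def L(self) -> int:
        return self.lambdas.shape[0]

    def predict(self, X, index: int):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefs[index] + self.intercepts[index]


def fit_path(X, y, lambdas, alpha: float = 0.9, tol: float = 1e-7,
             max_iter: int = 100_000) -> RegularizationPathFit:
    """Warm-started coordinate-descent sweep from the largest to the
    smallest lambda, with KKT stationarity checked at every solution."""
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambdas must be strictly decreasing")
    std = _Standardized(X, y)
    L = lambdas.shape[0]
    coefs = np.zeros((L, std.p))
    intercepts = np.zeros(L)
    beta_std = np.zeros(std.p)
    kkt = 0.0
    for l, lam in enumerate(lambdas):
        _cd_gram(std.G, std.c, lam * alpha, lam * (1 - alpha), beta_std,
                 tol, max_iter)
        kkt = max(kkt, std.kkt_violation(beta_std, lam, alpha))
        coefs[l], intercepts[l] = std.unstandardize(beta_std)
    n_nonzero = np.count_nonzero(coefs, axis=1)
    return RegularizationPathFit(
        lambdas=lambdas, alpha=float(alpha), coefs=coefs,
        intercepts=intercepts, n_nonzero=n_nonzero, kkt_max_violation=kkt,
    )
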