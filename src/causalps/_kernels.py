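"""Numba-compiled numerical kernels.

These are the hot paths of the Monte-Carlo study: a logistic-regression
Newton/IRLS solver, an all-subsets Gaussian-AIC search driven by the Gram
matrix, and a covariance-update coordinate-descent lasso path. Each is
called O(10^5) times inside bootstrap-within-trial loops, which is why they
are compiled rather than delegated to the usual model-fitting libraries
(those remain as cross-checking oracles in the test suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "logistic_irls",
    "best_subset_aic",
    "lasso_path_gram",
]


@njit(cache=False)
def logistic_irls(X, z, tol, max_iter):
    """Newton/IRLS maximum-likelihood logistic regression.

    X must include any intercept column. Returns (beta, converged,
    separated). `separated` flags a diverging coefficient norm, the
    signature of (quasi-)complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -1.0e300
    converged = False
    for _ in range(max_iter):
        eta = X.dot(beta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        for i in range(n):
            if w[i] < 1e-12:
                w[i] = 1e-12
        XtW = X.T * w
        H = XtW.dot(X)
        g = X.T.dot(z - mu)
        step = np.linalg.solve(H, g)
        beta = beta + step
        # observed-data log-likelihood at the new beta, overflow-safe
        eta = X.dot(beta)
        ll = 0.0
        for i in range(n):
            e = eta[i]
            if e > 30.0:
                sp = e
            elif e < -30.0:
                sp = 0.0
            else:
                sp = np.log1p(np.exp(e))
            ll += z[i] * e - sp
        if np.abs(ll - ll_old) < tol * (np.abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    separated = np.abs(beta).max() > 1.0e2
    return beta, converged, separated


@njit(cache=False)
def best_subset_aic(G, a, yty, n, masks, n_pred):
    """Exhaustive subset search minimising Gaussian AIC.

    G is the (1+n_pred) x (1+n_pred) Gram matrix of the design
    [intercept, predictors], a = design' y, yty = y'y. `masks` enumerates
    predictor subsets as bitmasks ordered by increasing size so that AIC
    ties resolve toward the smaller model. AIC counts intercept, slopes
    and the error variance among the parameters.

    Returns (best_aic, best_mask, best_coefs) with best_coefs aligned to
    the full design columns (zeros for excluded predictors).
    """
    m = G.shape[0]
    best_aic = 1.0e300
    best_mask = 0
    best_coefs = np.zeros(m)
    idx = np.empty(m, np.int64)
    log2pi = np.log(2.0 * np.pi)
    for t in range(masks.shape[0]):
        mask = masks[t]
        k = 1
        idx[0] = 0
        for j in range(n_pred):
            if (mask >> j) & 1:
                idx[k] = j + 1
                k += 1
        Gs = np.empty((k, k))
        asub = np.empty(k)
        for r in range(k):
            asub[r] = a[idx[r]]
            for c in range(k):
                Gs[r, c] = G[idx[r], idx[c]]
        beta = np.linalg.solve(Gs, asub)
        rss = yty
        for r in range(k):
            rss -= beta[r] * asub[r]
        if rss < 1e-12:
            rss = 1e-12
        sig2 = rss / n
        ll = -0.5 * n * (log2pi + np.log(sig2) + 1.0)
        aic = -2.0 * ll + 2.0 * (k + 1.0)
        if aic < best_aic:
            best_aic = aic
            best_mask = mask
            best_coefs[:] = 0.0
            for r in range(k):
                best_coefs[idx[r]] = beta[r]
    return best_aic, best_mask, best_coefs


@njit(cache=False)
def lasso_path_gram(G, c, lambdas, tol, max_iter):
    """Coordinate-descent lasso path on sufficient statistics.

    Solves argmin (1/2n)||y - Xb||^2 + lambda * ||b||_1 for a decreasing
    sequence of lambdas with warm starts, where G = X'X/n and c = X'y/n
    for centered y and standardized X (covariance updates; only the p x p
    moments are touched). Returns the (n_lambda, p) coefficient path on
    the standardized scale.
    """
    p = G.shape[0]
    nl = lambdas.shape[0]
    beta = np.zeros(p)
    out = np.zeros((nl, p))
    for l in range(nl):
        lam = lambdas[l]
        for _ in range(max_iter):
            dmax = 0.0
            for j in range(p):
                if G[j, j] <= 0.0:
                    beta[j] = 0.0
                    continue
                gj = c[j]
                for k in range(p):
                    if k != j:
                        gj -= G[j, k] * beta[k]
                if gj > lam:
                    bnew = (gj - lam) / G[j, j]
                elif gj < -lam:
                    bnew = (gj + lam) / G[j, j]
                else:
                    bnew = 0.0
                d = bnew - beta[j]
                if d != 0.0:
                    beta[j] = bnew
                    ad = np.abs(d)
                    if ad > dmax:
                        dmax = ad
            if dmax < tol:
                break
        out[l] = beta
    return out


def warmup() -> None:
    """Trigger JIT compilation of all kernels on toy inputs."""
    X = np.column_stack([np.ones(8), np.arange(8, dtype=float) - 3.5])
    z = (np.arange(8) % 2).astype(np.float64)
    logistic_irls(X, z, 1e-8, 50)
    G = X.T @ X
    a = X.T @ z
    masks = np.array([0, 1], dtype=np.int64)
    best_subset_aic(G, a, float(z @ z), 8, masks, 1)
    Gs = np.eye(2)
    c = np.array([0.5, -0.2])
    lasso_path_gram(Gs, c, np.array([0.4, 0.1]), 1e-9, 100)
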