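"""Uncertainty quantification and missing-data machinery.

* :func:`bootstrap_ci` — nonparametric bootstrap standard errors with
  normal-approximation (default) or percentile confidence intervals.
* :func:`little_mcar_test` — Little's chi-square test of the
  missing-completely-at-random hypothesis, built on a multivariate-normal
  EM estimate of the mean and covariance.
* :func:`multiple_impute` — EM-with-bootstrapping multiple imputation:
  each completed copy draws its (mu, Sigma) from an EM fit to a bootstrap
  resample and fills missing cells from the conditional normal given the
  row's observed cells.
* :func:`rubin_pool` — Rubin's rules for combining per-imputation
  estimates: total variance = within + (1 + 1/m) * between.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .dgp import FieldDataset
from .estimators import (
    EffectEstimate,
    estimate_aic_best,
    estimate_ipw,
    estimate_lasso,
    estimate_ow,
)

__all__ = [
    "bootstrap_ci",
    "little_mcar_test",
    "MCARResult",
    "multiple_impute",
    "ImputationSet",
    "rubin_pool",
    "PooledEstimate",
    "em_norm",
]

_NAMED_ESTIMATORS: dict[str, Callable] = {
    "ipw": estimate_ipw,
    "ow": estimate_ow,
    "aic": estimate_aic_best,
    "lasso": estimate_lasso,
}


def _unpack(data):
    if hasattr(data, "y") and hasattr(data, "z") and hasattr(data, "x"):
        return (data.y, data.z, data.x)
    if isinstance(data, (tuple, list)):
        return tuple(np.asarray(a) if a is not None else None for a in data)
    return (np.asarray(data),)


def _call_estimator(fn, arrays, rng):
    try:
        out = fn(*arrays, seed=rng)
    except TypeError:
        out = fn(*arrays)
    return out.point if isinstance(out, EffectEstimate) else float(out)


def bootstrap_ci(
    data,
    estimator,
    n_boot: int = 1000,
    seed=None,
    level: float = 0.95,
    percentile: bool = False,
    max_failure_rate: float = 0.5,
    groups=None,
) -> EffectEstimate:
    """Bootstrap SE and confidence interval for an effect estimator.

    ``data`` is a (y, z, x) triple / SimDataset (rows resampled jointly)
    or a bare array; ``estimator`` is a name in {ipw, ow, aic, lasso} or a
    callable taking the same arrays (plus an optional ``seed``). Resamples
    with a single treatment class are redrawn (counted in the metadata);
    resamples on which the estimator raises are dropped, and a failure
    rate above ``max_failure_rate`` aborts. ``groups`` switches to a
    cluster bootstrap: whole groups are resampled with replacement.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    arrays = _unpack(data)
    n = arrays[0].shape[0]
    fn = _NAMED_ESTIMATORS[estimator] if isinstance(estimator, str) else estimator
    method = estimator if isinstance(estimator, str) else "ow_regression"
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    point = _call_estimator(fn, arrays, rng)
    z = arrays[1] if len(arrays) > 1 else None
    if groups is not None:
        groups = np.asarray(groups)
        gids = np.unique(groups)
        members = [np.nonzero(groups == g)[0] for g in gids]

    ests = np.empty(n_boot)
    n_ok = 0
    redraws = 0
    failures = 0
    for _ in range(n_boot):
        for _attempt in range(1000):
            if groups is None:
                idx = rng.integers(0, n, n)
            else:
                drawn = rng.integers(0, len(gids), len(gids))
                idx = np.concatenate([members[g] for g in drawn])
            if z is None or 0 < z[idx].sum() < idx.size:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a resample containing both treatment classes")
        sub = tuple(a[idx] if a is not None else None for a in arrays)
        try:
            ests[n_ok] = _call_estimator(fn, sub, rng)
            n_ok += 1
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"estimator failed on {failures}/{n_boot} bootstrap resamples")
    ests = ests[:n_ok]
    se = float(ests.std(ddof=1)) if n_ok > 1 else 0.0
    if percentile:
        alpha = 1.0 - level
        lo, hi = np.quantile(ests, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(lo, point), max(hi, point)
    else:
        zq = stats.norm.ppf(0.5 + level / 2)
        lo, hi = point - zq * se, point + zq * se
    return EffectEstimate(
        method=method if isinstance(method, str) else "ow_regression",
        point=point,
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        meta={"n_boot": n_boot, "n_failed": failures, "n_redrawn": redraws, "percentile": percentile},
    )


# ---------------------------------------------------------------------------
# Multivariate-normal EM
# ---------------------------------------------------------------------------


def _patterns(mask: np.ndarray):
    """Group row indices by missingness pattern (rows with no observed
    values are returned separately)."""
    order = np.lexsort(mask.T[::-1])
    sorted_mask = mask[order]
    change = np.any(sorted_mask[1:] != sorted_mask[:-1], axis=1)
    starts = np.concatenate([[0], np.nonzero(change)[0] + 1, [mask.shape[0]]])
    groups = []
    for s, e in zip(starts[:-1], starts[1:]):
        groups.append((sorted_mask[s], order[s:e]))
    return groups


def _solve_psd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for a (near-)PSD A, ridge-stabilizing on singularity."""
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        eps = 1e-10 * (np.trace(A) / A.shape[0] + 1e-12)
        return np.linalg.solve(A + eps * np.eye(A.shape[0]), B)


def em_norm(Y: np.ndarray, tol: float = 1e-7, max_iter: int = 500, param_tol: float = 1e-5):
    """ML mean/covariance of a multivariate normal with missing values.

    Returns (mu, Sigma, loglik, n_iter, converged); Sigma uses the ML
    (divide-by-n) convention. Columns with no observed values are
    rejected. Convergence is declared on a relative log-likelihood change
    below ``tol`` or, secondarily, when the parameters stop moving
    (relative change below ``param_tol``) — the latter handles
    near-degenerate data (e.g. cluster-constant columns under bootstrap
    resampling) where the likelihood drifts along a singular ridge.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    miss = np.isnan(Y)
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing; it cannot be estimated")
    mu = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0)
    var = np.maximum(var, 1e-8)
    Sigma = np.diag(var)
    par_scale = np.sqrt(np.outer(var, var))
    sd0 = np.sqrt(var)
    groups = _patterns(miss)
    ll_old = -np.inf
    converged = False
    it = 0
    ll = np.nan
    for it in range(1, max_iter + 1):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        ll = 0.0
        for pat, rows in groups:
            O = np.nonzero(~pat)[0]
            M = np.nonzero(pat)[0]
            nr = rows.size
            if O.size == 0:
                S1 += nr * mu
                S2 += nr * (Sigma + np.outer(mu, mu))
                continue
            Yo = Y[np.ix_(rows, O)]
            Soo = Sigma[np.ix_(O, O)]
            dev = Yo - mu[O]
            sign, logdet = np.linalg.slogdet(Soo)
            sol = _solve_psd(Soo, dev.T)  # (|O|, nr)
            ll += -0.5 * (nr * (O.size * np.log(2 * np.pi) + logdet) + np.sum(dev.T * sol))
            S1[O] += Yo.sum(axis=0)
            S2[np.ix_(O, O)] += Yo.T @ Yo
            if M.size:
                K = _solve_psd(Soo, Sigma[np.ix_(O, M)])  # (|O|, |M|)
                cond = mu[M] + dev @ K  # (nr, |M|)
                C = Sigma[np.ix_(M, M)] - Sigma[np.ix_(M, O)] @ K
                S1[M] += cond.sum(axis=0)
                cross = Yo.T @ cond
                S2[np.ix_(O, M)] += cross
                S2[np.ix_(M, O)] += cross.T
                S2[np.ix_(M, M)] += cond.T @ cond + nr * C
        mu_new = S1 / n
        Sigma_new = S2 / n - np.outer(mu_new, mu_new)
        Sigma_new = 0.5 * (Sigma_new + Sigma_new.T)
        dpar = max(
            float(np.max(np.abs(mu_new - mu) / (sd0 + 1e-12))),
            float(np.max(np.abs(Sigma_new - Sigma) / (par_scale + 1e-12))),
        )
        mu, Sigma = mu_new, Sigma_new
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0) or dpar < param_tol:
            converged = True
            break
        ll_old = ll
    return mu, Sigma, ll, it, converged


class MCARResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def little_mcar_test(data, tol: float = 1e-7, max_iter: int = 500) -> MCARResult:
    """Little's chi-square test of missing-completely-at-random.

    With EM estimates (mu, Sigma), each missingness pattern j contributes
    d2_j = n_j (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j) restricted to
    its observed columns; the statistic sums d2_j over patterns and is
    referred to chi-square with df = sum_j p_j - p. Complete data returns
    (0, 0, p=1).
    """
    Y = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("need a 2-D array with at least two columns")
    miss = np.isnan(Y)
    keep = ~miss.all(axis=1)
    Y, miss = Y[keep], miss[keep]
    p = Y.shape[1]
    if not miss.any():
        return MCARResult(0.0, 0, 1.0)
    mu, Sigma, *_ = em_norm(Y, tol=tol, max_iter=max_iter)
    stat = 0.0
    df = -p
    for pat, rows in _patterns(miss):
        O = np.nonzero(~pat)[0]
        ybar = Y[np.ix_(rows, O)].mean(axis=0)
        dev = ybar - mu[O]
        Soo = Sigma[np.ix_(O, O)]
        try:
            sol = np.linalg.solve(Soo, dev)
        except np.linalg.LinAlgError:
            eps = 1e-8 * np.trace(Soo) / O.size
            warnings.warn(f"singular restricted covariance; ridge-stabilized with eps={eps:.3g}")
            sol = np.linalg.solve(Soo + eps * np.eye(O.size), dev)
        stat += rows.size * float(dev @ sol)
        df += O.size
    df = int(df)
    pval = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return MCARResult(float(stat), df, pval)


# ---------------------------------------------------------------------------
# Multiple imputation (EM with bootstrapping)
# ---------------------------------------------------------------------------


@dataclass
class ImputationSet:
    """m completed copies of a dataset plus provenance.

    Copies are FieldDatasets when the input was one, otherwise DataFrames.
    Observed cells are identical across copies and to the source.
    """

    datasets: list
    provenance: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)


def _impute_once(Y, miss, mu, Sigma, rng):
    out = Y.copy()
    for pat, rows in _patterns(miss):
        M = np.nonzero(pat)[0]
        if M.size == 0:
            continue
        O = np.nonzero(~pat)[0]
        if O.size:
            Soo = Sigma[np.ix_(O, O)]
            K = np.linalg.solve(Soo, Sigma[np.ix_(O, M)])
            cond = mu[M] + (Y[np.ix_(rows, O)] - mu[O]) @ K
            C = Sigma[np.ix_(M, M)] - Sigma[np.ix_(M, O)] @ K
        else:
            cond = np.tile(mu[M], (rows.size, 1))
            C = Sigma[np.ix_(M, M)]
        C = 0.5 * (C + C.T)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            # degenerate conditional covariance: draw on its PSD projection
            w, V = np.linalg.eigh(C)
            L = V * np.sqrt(np.maximum(w, 0.0))
        draws = cond + rng.standard_normal((rows.size, M.size)) @ L.T
        out[np.ix_(rows, M)] = draws
    return out


def multiple_impute(
    data, m: int, seed=None, tol: float = 1e-7, max_iter: int = 500, columns=None
) -> ImputationSet:
    """EM-with-bootstrapping multiple imputation under joint normality.

    For each of the m copies: bootstrap the rows, fit (mu*, Sigma*) by EM,
    then fill each *original* row's missing cells with one draw from the
    conditional normal given its observed cells. Complete input yields m
    identical copies. Copies whose EM did not converge are flagged and —
    when more than 10% fail — dropped with a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    is_field = isinstance(data, FieldDataset)
    if is_field:
        cols = [data.roles["treatment"], *data.numeric_frame().columns]
        frame = data.frame
    else:
        frame = pd.DataFrame(data)
        cols = [c for c in frame.columns if np.issubdtype(frame[c].dtype, np.number)]
    if columns is not None:
        cols = list(columns)
    Y = frame[cols].to_numpy(dtype=float)
    miss = np.isnan(Y)
    if miss.all(axis=0).any():
        bad = [cols[j] for j in np.nonzero(miss.all(axis=0))[0]]
        raise ValueError(f"columns entirely missing: {bad}")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(m)
    copies, flags, iters = [], [], []
    n = Y.shape[0]
    for k in range(m):
        rng = np.random.default_rng(children[k])
        if not miss.any():
            filled, ok, it = Y, True, 0
        else:
            boot = rng.integers(0, n, n)
            mu_s, Sig_s, _, it, ok = em_norm(Y[boot], tol=tol, max_iter=max_iter)
            filled = _impute_once(Y, miss, mu_s, Sig_s, rng)
        new = frame.copy()
        new[cols] = filled
        copies.append(data.copy_with(new) if is_field else new)
        flags.append(bool(ok))
        iters.append(int(it))
    n_bad = flags.count(False)
    if 0.1 * m < n_bad < m:
        warnings.warn(f"{n_bad}/{m} imputations failed EM convergence and were excluded")
        copies = [c for c, ok in zip(copies, flags) if ok]
    elif n_bad == m:
        warnings.warn(f"EM failed to converge for all {m} imputations; keeping flagged copies")
    prov = {"seed_entropy": ss.entropy, "em_iterations": iters, "converged": flags, "m_requested": m}
    return ImputationSet(datasets=copies, provenance=prov)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


@dataclass
class PooledEstimate:
    point: float
    total_variance: float
    se: float
    ci_low: float
    ci_high: float
    m: int
    within: float = 0.0
    between: float = 0.0

    def __post_init__(self):
        if self.total_variance + 1e-12 < self.within:
            raise ValueError("total variance cannot fall below the mean within-imputation variance")


def rubin_pool(points, ses, level: float = 0.95) -> PooledEstimate:
    """Combine per-imputation estimates by Rubin's rules.

    qbar = mean(points); W = mean(ses^2); B = var(points, ddof=1);
    T = W + (1 + 1/m) B; the CI uses normal quantiles around qbar.
    """
    points = np.asarray(points, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if points.ndim != 1 or points.shape != ses.shape or points.size < 1:
        raise ValueError("points and ses must be equal-length 1-D vectors")
    if (ses < 0).any():
        raise ValueError("standard errors must be nonnegative")
    m = points.size
    q = float(points.mean())
    W = float(np.mean(ses**2))
    if m == 1:
        warnings.warn("m=1: between-imputation variance is undefined; returning the single estimate")
        B = 0.0
    else:
        B = float(points.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    se = float(np.sqrt(T))
    zq = stats.norm.ppf(0.5 + level / 2)
    return PooledEstimate(
        point=q,
        total_variance=T,
        se=se,
        ci_low=q - zq * se,
        ci_high=q + zq * se,
        m=m,
        within=W,
        between=B,
    )
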