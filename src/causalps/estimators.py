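"""Treatment-effect estimators.

Four competing estimates of the same causal contrast (the difference of a
unit's potential outcomes under treatment vs control):

* :func:`estimate_ipw` — Hajek-normalized inverse-probability-weighted
  difference of group means, scores from logistic regression on all
  covariates;
* :func:`estimate_ow`  — the analogous overlap-weighted difference
  (treated weighted by 1-e, controls by e);
* :func:`estimate_aic_best` — the treatment coefficient from the
  minimum-AIC ordinary-least-squares model among all subsets of
  {treatment, covariates} (0 when the treatment is excluded);
* :func:`estimate_lasso` — the treatment coefficient from an L1-penalized
  regression with the penalty chosen by k-fold cross-validation (the
  treatment's coefficient is penalized like any other).

The first two are causal estimators; the last two are the
prediction-oriented selection procedures they are benchmarked against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._kernels import best_subset_aic, lasso_path_gram
from .propensity import PropensityFit, compute_weights, fit_propensity

__all__ = [
    "EffectEstimate",
    "estimate_ipw",
    "estimate_ow",
    "estimate_aic_best",
    "estimate_lasso",
    "ow_weighted_regression",
    "lasso_coefficients",
]

_METHODS = ("ipw", "ow", "aic", "lasso", "ow_regression")


@dataclass
class EffectEstimate:
    method: str
    point: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.point <= self.ci_high):
                raise ValueError("point estimate must lie inside its confidence interval")


def _as_xy(y, z, x):
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.shape[0]:
        x = x.T
    return y, z, x


# ---------------------------------------------------------------------------
# Weighted-mean-difference estimators
# ---------------------------------------------------------------------------


def _point_ipw(y: np.ndarray, z: np.ndarray, e: np.ndarray) -> float:
    wt = z / e
    wc = (1.0 - z) / (1.0 - e)
    return float(wt @ y / wt.sum() - wc @ y / wc.sum())


def _point_ow(y: np.ndarray, z: np.ndarray, e: np.ndarray) -> float:
    wt = z * (1.0 - e)
    wc = (1.0 - z) * e
    return float(wt @ y / wt.sum() - wc @ y / wc.sum())


def _weighted_estimate(method, y, z, x, scores, seed):
    y, z, x = _as_xy(y, z, x)
    meta = {}
    if scores is None:
        fit = fit_propensity(z, x)
        e = fit.scores
        meta["ps_coefficients"] = fit.coefficients
    else:
        e = scores.scores if isinstance(scores, PropensityFit) else np.asarray(scores, dtype=float)
        meta["ps_source"] = "supplied"
    point = _point_ipw(y, z, e) if method == "ipw" else _point_ow(y, z, e)
    return EffectEstimate(method=method, point=point, meta=meta)


def estimate_ipw(y, z, x, scores=None, seed=None) -> EffectEstimate:
    """Hajek-normalized IPW difference of weighted group means.

    ``scores`` may supply known propensity scores (e.g. the true
    assignment probabilities); by default they are estimated by logistic
    regression on all columns of ``x``.
    """
    return _weighted_estimate("ipw", y, z, x, scores, seed)


def estimate_ow(y, z, x, scores=None, seed=None) -> EffectEstimate:
    """Normalized overlap-weighted difference (treated by 1-e, controls by e)."""
    return _weighted_estimate("ow", y, z, x, scores, seed)


# ---------------------------------------------------------------------------
# All-subsets AIC
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _subset_masks(n_pred: int) -> np.ndarray:
    masks = sorted(range(1 << n_pred), key=lambda m: (bin(m).count("1"), m))
    return np.asarray(masks, dtype=np.int64)


def _drop_collinear(D: np.ndarray, names: list) -> tuple[np.ndarray, list]:
    keep, kept_cols = [], [np.ones(D.shape[0])]
    for j in range(D.shape[1]):
        trial = np.column_stack(kept_cols + [D[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
            kept_cols.append(D[:, j])
        else:
            warnings.warn(f"dropping collinear predictor {names[j]!r} from the subset search")
    return D[:, keep], [names[j] for j in keep]


def _aic_search(y: np.ndarray, D: np.ndarray, names: list):
    n = y.shape[0]
    design = np.ascontiguousarray(np.column_stack([np.ones(n), D]))
    G = design.T @ design
    a = design.T @ y
    masks = _subset_masks(D.shape[1])
    try:
        return best_subset_aic(G, a, float(y @ y), n, masks, D.shape[1]), names
    except np.linalg.LinAlgError:
        D2, names2 = _drop_collinear(D, names)
        if D2.shape[1] == D.shape[1]:
            raise
        return _aic_search(y, D2, names2)


def estimate_aic_best(y, z, x, names=None) -> EffectEstimate:
    """Treatment coefficient from the minimum-AIC OLS model.

    Enumerates all 2^p OLS models over {treatment, covariates} (intercept
    always included); AIC = -2 * maximized Gaussian log-likelihood +
    2 * (slopes + intercept + error variance). Ties resolve toward the
    smaller model. When the selected model excludes the treatment, the
    returned point estimate is 0 with ``meta['treatment_selected']`` False.
    """
    y, z, x = _as_xy(y, z, x)
    if names is None:
        names = ["Z"] + [f"X{j + 1}" for j in range(x.shape[1])]
    D = np.column_stack([z, x])
    if y.shape[0] <= D.shape[1] + 2:
        raise ValueError("need more observations than candidate predictors + 2")
    (best_aic_val, best_mask, coefs), names = _aic_search(y, D, list(names))
    selected = [names[j] for j in range(len(names)) if (best_mask >> j) & 1]
    z_in = names[0] in selected
    point = float(coefs[1]) if z_in else 0.0
    return EffectEstimate(
        method="aic",
        point=point,
        meta={"aic": float(best_aic_val), "selected": selected, "treatment_selected": z_in},
    )


# ---------------------------------------------------------------------------
# Cross-validated lasso
# ---------------------------------------------------------------------------

_LASSO_TOL = 1e-9
_LASSO_MAXIT = 10_000
_N_LAMBDA = 100
_LAMBDA_MIN_RATIO = 1e-4


def _standardize_stats(D: np.ndarray):
    mx = D.mean(axis=0)
    sx = np.sqrt(((D - mx) ** 2).mean(axis=0))  # 1/n convention
    sx_safe = np.where(sx > 0, sx, 1.0)
    return mx, sx, sx_safe


def lasso_coefficients(y, D, lam: float):
    """Lasso fit at a fixed penalty: minimize (1/2n)RSS + lam * ||slopes||_1.

    Predictors are standardized internally (mean 0, 1/n-convention SD 1);
    the returned (intercept, slopes) are on the original scale.
    """
    y = np.asarray(y, dtype=float)
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if D.shape[0] != y.shape[0]:
        D = D.T
    my = y.mean()
    mx, sx, sx_safe = _standardize_stats(D)
    Ds = (D - mx) / sx_safe
    n = y.shape[0]
    G = np.ascontiguousarray(Ds.T @ Ds / n)
    c = np.ascontiguousarray(Ds.T @ (y - my) / n)
    betas = lasso_path_gram(G, c, np.array([float(lam)]), _LASSO_TOL, _LASSO_MAXIT)[0]
    slopes = np.where(sx > 0, betas / sx_safe, 0.0)
    intercept = my - slopes @ mx
    return float(intercept), slopes


def _fold_assignments(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.resize(np.arange(n_folds), n)
    rng.shuffle(folds)
    return folds


def _cv_lasso(y: np.ndarray, D: np.ndarray, n_folds: int, rng: np.random.Generator):
    """k-fold CV over a 100-point log-spaced lambda path; returns
    (lambdas, cv_mse, best_index, slopes_at_best_on_original_scale)."""
    n, p = D.shape
    # total and per-fold moment matrices; everything downstream is O(p^2)
    folds = _fold_assignments(n, n_folds, rng)
    Sx_t = D.sum(axis=0)
    Sxx_t = D.T @ D
    Sxy_t = D.T @ y
    Sy_t = y.sum()
    Syy_t = float(y @ y)

    mx, sx, sx_safe = _standardize_stats(D)
    c_full = ((Sxy_t / n) - mx * (Sy_t / n)) / sx_safe
    c_full = np.where(sx > 0, c_full, 0.0)
    lam_max = float(np.max(np.abs(c_full)))
    if np.var(y) == 0 or lam_max <= 1e-12 * max(1.0, float(np.abs(y).max())):
        warnings.warn("outcome is constant (or orthogonal to all predictors); all lasso slopes are 0")
        return np.zeros(1), np.zeros(1), 0, np.zeros(p)
    lambdas = np.geomspace(lam_max, lam_max * _LAMBDA_MIN_RATIO, _N_LAMBDA)

    cv_sse = np.zeros(_N_LAMBDA)
    for f in range(n_folds):
        in_f = folds == f
        nf = int(in_f.sum())
        if nf == 0 or nf == n:
            continue
        Df, yf = D[in_f], y[in_f]
        Sx_f, Sxx_f, Sxy_f = Df.sum(axis=0), Df.T @ Df, Df.T @ yf
        Sy_f, Syy_f = yf.sum(), float(yf @ yf)
        ntr = n - nf
        mx_tr = (Sx_t - Sx_f) / ntr
        my_tr = (Sy_t - Sy_f) / ntr
        var_tr = np.diag(Sxx_t - Sxx_f) / ntr - mx_tr**2
        s_tr = np.sqrt(np.maximum(var_tr, 0.0))
        s_safe = np.where(s_tr > 0, s_tr, 1.0)
        Cov_tr = (Sxx_t - Sxx_f) / ntr - np.outer(mx_tr, mx_tr)
        G = np.ascontiguousarray(Cov_tr / np.outer(s_safe, s_safe))
        c = ((Sxy_t - Sxy_f) / ntr - mx_tr * my_tr) / s_safe
        c = np.ascontiguousarray(np.where(s_tr > 0, c, 0.0))
        betas = lasso_path_gram(G, c, lambdas, _LASSO_TOL, _LASSO_MAXIT)
        B = np.where(s_tr > 0, betas / s_safe, 0.0)  # (L, p) original scale
        b0 = my_tr - B @ mx_tr  # (L,)
        sse = (
            Syy_f
            - 2.0 * b0 * Sy_f
            - 2.0 * (B @ Sxy_f)
            + nf * b0**2
            + 2.0 * b0 * (B @ Sx_f)
            + np.einsum("lp,pq,lq->l", B, Sxx_f, B)
        )
        cv_sse += sse
    cv_mse = cv_sse / n
    best = int(np.argmin(cv_mse))

    # final fit on the full data along the same path
    Gf = np.ascontiguousarray((Sxx_t / n - np.outer(mx, mx)) / np.outer(sx_safe, sx_safe))
    betas = lasso_path_gram(Gf, np.ascontiguousarray(c_full), lambdas, _LASSO_TOL, _LASSO_MAXIT)
    slopes = np.where(sx > 0, betas[best] / sx_safe, 0.0)
    return lambdas, cv_mse, best, slopes


def estimate_lasso(y, z, x, n_folds: int = 10, seed=None) -> EffectEstimate:
    """Treatment coefficient from cross-validated L1-penalized regression.

    The penalty path runs over 100 log-spaced values from lambda_max (the
    smallest penalty shrinking every slope to zero) down to
    lambda_max * 1e-4; the value minimizing the mean k-fold CV error is
    selected (ties toward the larger penalty). Fold assignment is seeded.
    """
    y, z, x = _as_xy(y, z, x)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D = np.column_stack([z, x])
    lambdas, cv_mse, best, slopes = _cv_lasso(y, D, n_folds, rng)
    return EffectEstimate(
        method="lasso",
        point=float(slopes[0]),
        meta={
            "lambda": float(lambdas[best]),
            "cv_mse": float(cv_mse[best]),
            "n_folds": n_folds,
            "n_nonzero": int(np.count_nonzero(slopes)),
        },
    )


# ---------------------------------------------------------------------------
# Weighted outcome regression
# ---------------------------------------------------------------------------


def ow_weighted_regression(y, z, x_cov=None, weights=None, names=None) -> EffectEstimate:
    """Weighted least squares of the outcome on treatment + covariates.

    This is the case-study outcome model: each observation carries its
    overlap weight and the returned estimate is the treatment coefficient.
    ``x_cov`` may be None/empty, in which case the fit reduces to the
    overlap-weighted difference of group means.
    """
    import statsmodels.api as sm

    from .propensity import WeightVector

    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if weights is None:
        w = np.ones_like(y)
    elif isinstance(weights, WeightVector):
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=float)
    if x_cov is None or (hasattr(x_cov, "size") and np.asarray(x_cov).size == 0):
        D = z.reshape(-1, 1)
    else:
        x_cov = np.atleast_2d(np.asarray(x_cov, dtype=float))
        if x_cov.shape[0] != y.shape[0]:
            x_cov = x_cov.T
        D = np.column_stack([z, x_cov])
    design = sm.add_constant(D, has_constant="add")
    res = sm.WLS(y, design, weights=w).fit()
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient design in weighted regression; coefficients from pseudoinverse")
    return EffectEstimate(method="ow_regression", point=float(res.params[1]), meta={"nobs": int(res.nobs)})
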