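"""Propensity-score estimation, weighting schemes and balance diagnostics.

The propensity score e_i = Pr(z_i = 1 | x_i) is fit by maximum-likelihood
logistic regression (Newton/IRLS). Two weighting schemes are provided:

* ``ipw``      w_i = z_i/e_i + (1-z_i)/(1-e_i)      (targets the ATE)
* ``overlap``  w_i = z_i(1-e_i) + (1-z_i)e_i        (targets the ATO)

Overlap weights built from a converged logistic fit balance the weighted
mean of every covariate in the score model *exactly* — the score equations
sum(z_i - e_i) x_i = 0 make the weighted treated and control means equal —
which is the mechanism behind post-weighting standardized mean differences
collapsing to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import logistic_irls

__all__ = [
    "PropensityFit",
    "WeightVector",
    "BalanceReport",
    "SeparationError",
    "fit_propensity",
    "compute_weights",
    "standardized_mean_difference",
    "balance_report",
]


class SeparationError(RuntimeError):
    """Raised when the logistic MLE diverges (complete or quasi separation)."""


@dataclass
class PropensityFit:
    coefficients: np.ndarray  # intercept first
    scores: np.ndarray
    converged: bool
    covariate_names: list

    def __post_init__(self):
        if not ((self.scores > 0) & (self.scores < 1)).all():
            raise ValueError("propensity scores must lie strictly in (0, 1)")


@dataclass
class WeightVector:
    weights: np.ndarray
    scheme: str

    def __post_init__(self):
        if self.scheme not in ("ipw", "overlap"):
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")


def _validate_treatment(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if not np.isin(z, (0.0, 1.0)).all():
        raise ValueError("treatment vector must contain only 0/1")
    if z.min() == z.max():
        raise ValueError("treatment has no variation")
    return z


def fit_propensity(
    z,
    x,
    covariate_names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PropensityFit:
    """Maximum-likelihood logistic regression of treatment on covariates.

    An intercept is always included. Convergence is declared on a relative
    log-likelihood change below ``tol``; a diverging coefficient norm is
    reported as :class:`SeparationError` rather than silently returning
    degenerate 0/1 scores.
    """
    z = _validate_treatment(z)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != z.shape[0]:
        x = x.T
    if np.isnan(x).any() or not np.isfinite(x).all():
        raise ValueError("covariate matrix contains missing or non-finite values")
    if covariate_names is None:
        covariate_names = [f"X{j + 1}" for j in range(x.shape[1])]
    # constant columns carry no information and would make the Hessian
    # singular; they keep a zero coefficient
    active = np.nonzero(x.std(axis=0) > 0)[0]
    design = np.ascontiguousarray(np.column_stack([np.ones(z.shape[0]), x[:, active]]))
    try:
        beta_a, converged, separated = logistic_irls(design, z, tol, max_iter)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"collinear covariates in the propensity model: {err}") from err
    beta = np.zeros(x.shape[1] + 1)
    beta[0] = beta_a[0]
    beta[active + 1] = beta_a[1:]
    if separated or not np.isfinite(beta).all():
        j = int(np.argmax(np.abs(beta[1:])))
        raise SeparationError(
            "complete or quasi-complete separation detected in the propensity model; "
            f"coefficients diverge along covariate {covariate_names[j]!r}"
        )
    eta = np.column_stack([np.ones(z.shape[0]), x]) @ beta
    scores = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1.0 - 1e-12)
    return PropensityFit(
        coefficients=beta,
        scores=scores,
        converged=bool(converged),
        covariate_names=list(covariate_names),
    )


def _scores_of(fit_or_scores) -> np.ndarray:
    e = fit_or_scores.scores if isinstance(fit_or_scores, PropensityFit) else np.asarray(fit_or_scores, dtype=float)
    if not ((e > 0) & (e < 1)).all():
        raise ValueError("scores must lie strictly in (0, 1)")
    return e


def compute_weights(fit, z, scheme: str = "overlap", trim_threshold: float | None = None) -> WeightVector:
    """Form IPW or overlap weights from fitted scores.

    ``trim_threshold`` optionally truncates scores to
    [threshold, 1-threshold] before inverse weighting (off by default; the
    benchmark applies no trimming).
    """
    e = _scores_of(fit)
    z = np.asarray(z, dtype=float)
    if trim_threshold is not None:
        e = np.clip(e, trim_threshold, 1.0 - trim_threshold)
    if scheme == "ipw":
        w = z / e + (1.0 - z) / (1.0 - e)
    elif scheme == "overlap":
        w = z * (1.0 - e) + (1.0 - z) * e
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return WeightVector(weights=w, scheme=scheme)


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    m = float(np.sum(w * x) / sw)
    denom = sw - 1.0
    if denom <= 0:
        # single effective observation: variance undefined, treat as 0
        return m, 0.0
    v = float(np.sum(w * (x - m) ** 2) / denom)
    return m, v


def standardized_mean_difference(xcol, z, weights: WeightVector | np.ndarray | None = None) -> float:
    """Absolute standardized mean difference of one covariate.

    |m1 - m0| / sqrt((s1^2 + s0^2)/2) with (optionally weighted) group
    means and frequency-weight sample variances; unweighted when
    ``weights`` is omitted.
    """
    x = np.asarray(xcol, dtype=float)
    z = np.asarray(z, dtype=float)
    w = weights.weights if isinstance(weights, WeightVector) else weights
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    t, c = z == 1, z == 0
    if not t.any() or not c.any():
        raise ValueError("both treatment groups must be non-empty")
    if w[t].sum() <= 0 or w[c].sum() <= 0:
        raise ValueError("both groups need positive total weight")
    m1, v1 = _weighted_mean_var(x[t], w[t])
    m0, v0 = _weighted_mean_var(x[c], w[c])
    pooled = 0.5 * (v1 + v0)
    if pooled <= 0:
        raise ValueError("degenerate covariate: zero pooled variance")
    return abs(m1 - m0) / np.sqrt(pooled)


@dataclass
class BalanceReport:
    """Per-covariate unweighted vs weighted standardized mean differences."""

    table: pd.DataFrame  # columns: covariate, smd_unweighted, smd_weighted
    scheme: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, ax=None):
        """Dot plot of SMDs with reference lines at 0.0 and 0.2."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.5 * len(self.table) + 1))
        ypos = np.arange(len(self.table))[::-1]
        ax.scatter(self.table["smd_unweighted"], ypos, marker="^", label="unweighted")
        ax.scatter(self.table["smd_weighted"], ypos, marker="o", label=f"{self.scheme}-weighted")
        for ref in (0.0, 0.2):
            ax.axvline(ref, ls="--", lw=0.8, color="grey")
        ax.set_yticks(ypos)
        ax.set_yticklabels(self.table["covariate"])
        ax.set_xlabel("standardized mean difference")
        ax.legend()
        return ax


def balance_report(x, z, weights: WeightVector, names: Sequence[str] | None = None) -> BalanceReport:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != np.asarray(z).shape[0]:
        x = x.T
    if names is None:
        names = [f"X{j + 1}" for j in range(x.shape[1])]
    rows = []
    for j, name in enumerate(names):
        try:
            raw = standardized_mean_difference(x[:, j], z)
            wtd = standardized_mean_difference(x[:, j], z, weights)
        except ValueError as err:
            warnings.warn(f"balance for {name!r} skipped: {err}")
            raw = wtd = np.nan
        rows.append((name, raw, wtd))
    table = pd.DataFrame(rows, columns=["covariate", "smd_unweighted", "smd_weighted"])
    return BalanceReport(table=table, scheme=weights.scheme)
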