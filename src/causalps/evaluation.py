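"""Monte-Carlo comparison of the four effect estimators.

:func:`run_simulation_study` repeats, for every requested (b, N) setting:
draw a dataset, compute each method's point estimate and (optionally) a
bootstrap confidence interval, and aggregate the trial mean and the
fraction of intervals covering the true effect. Bootstrap resamples are
shared across methods within a trial, and the propensity fit is shared
between the IPW and overlap estimates — a pure speed device; trials stay
independent.

Randomness is organized as one master seed spawning per-setting and
per-trial substreams, so any single trial can be reproduced in isolation
and results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dgp import DGPSetting, simulate_dgp
from .estimators import _point_ipw, _point_ow, estimate_aic_best, estimate_lasso
from .propensity import SeparationError, fit_propensity

__all__ = ["SimulationCell", "run_simulation_study", "bias_table", "coverage_table"]

_KNOWN_METHODS = ("ipw", "ow", "aic", "lasso")


@dataclass
class SimulationCell:
    """Aggregate of one (method, N, b) cell of the study."""

    method: str
    n_units: int
    b: float
    n_trials: int
    mean_estimate: float
    coverage: float  # nan when no CIs were formed
    mc_se_mean: float
    mc_se_coverage: float
    n_dropped: int = 0

    def __post_init__(self):
        if np.isfinite(self.coverage) and not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")


def _method_points(y, z, x, methods, rng, overrides, n_folds):
    """Point estimates for all methods on one (re)sample.

    Returns dict method -> float; a SeparationError poisons ipw and ow
    only (recorded as nan).
    """
    out = {}
    scores = None
    if "ipw" in methods or "ow" in methods:
        try:
            scores = fit_propensity(z, x).scores
        except SeparationError:
            scores = None
    for m in methods:
        if m in overrides:
            res = overrides[m](y, z, x, rng)
            out[m] = res.point if hasattr(res, "point") else float(res)
        elif m == "ipw":
            out[m] = _point_ipw(y, z, scores) if scores is not None else np.nan
        elif m == "ow":
            out[m] = _point_ow(y, z, scores) if scores is not None else np.nan
        elif m == "aic":
            out[m] = estimate_aic_best(y, z, x).point
        elif m == "lasso":
            out[m] = estimate_lasso(y, z, x, n_folds=n_folds, seed=rng).point
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


def run_simulation_study(
    grid: Sequence[DGPSetting] | DGPSetting,
    methods: Iterable[str] = _KNOWN_METHODS,
    n_trials: int = 1000,
    n_boot: int = 200,
    seed=None,
    level: float = 0.95,
    n_folds: int = 10,
    return_trials: bool = False,
    estimator_overrides: dict | None = None,
):
    """Run the full bias/coverage study.

    Parameters
    ----------
    grid
        One or more :class:`DGPSetting`; each setting's own ``seed`` field
        is replaced by per-trial substreams of ``seed``.
    methods
        Subset of {'ipw', 'ow', 'aic', 'lasso'} (plus any key of
        ``estimator_overrides``).
    n_boot
        Bootstrap replications per trial for the normal-approximation CI;
        0 skips interval construction (bias-only runs). With an override
        estimator returning its own interval, that interval is used
        directly when ``n_boot`` is 0.
    return_trials
        Also return the per-trial records (a tidy DataFrame) from which
        the cells can be re-derived.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    settings = [grid] if isinstance(grid, DGPSetting) else list(grid)
    methods = list(methods)
    overrides = estimator_overrides or {}
    zq = stats.norm.ppf(0.5 + level / 2)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    setting_streams = master.spawn(len(settings))

    records = []
    cells = []
    for si, setting in enumerate(settings):
        trial_streams = setting_streams[si].spawn(n_trials)
        per_method = {m: {"points": [], "covered": [], "dropped": 0} for m in methods}
        for t in range(n_trials):
            data_ss, est_ss = trial_streams[t].spawn(2)
            ds = simulate_dgp(setting.with_seed(int(data_ss.generate_state(1)[0] & 0x7FFFFFFF)))
            rng = np.random.default_rng(est_ss)
            points = _method_points(ds.y, ds.z, ds.x, methods, rng, overrides, n_folds)

            boot = {m: [] for m in methods}
            if n_boot > 0:
                n = ds.n
                for _ in range(n_boot):
                    for _attempt in range(1000):
                        idx = rng.integers(0, n, n)
                        if 0 < ds.z[idx].sum() < n:
                            break
                    else:  # pragma: no cover - astronomically unlikely
                        raise RuntimeError("could not draw a two-class resample")
                    bp = _method_points(ds.y[idx], ds.z[idx], ds.x[idx], methods, rng, overrides, n_folds)
                    for m in methods:
                        if np.isfinite(bp[m]):
                            boot[m].append(bp[m])

            for m in methods:
                pt = points[m]
                if not np.isfinite(pt):
                    per_method[m]["dropped"] += 1
                    continue
                se = lo = hi = np.nan
                if n_boot > 0 and len(boot[m]) > 1:
                    se = float(np.std(boot[m], ddof=1))
                    lo, hi = pt - zq * se, pt + zq * se
                elif n_boot == 0 and m in overrides:
                    res = overrides[m](ds.y, ds.z, ds.x, rng)
                    if getattr(res, "ci_low", None) is not None:
                        lo, hi = res.ci_low, res.ci_high
                covered = (lo <= setting.beta_cause <= hi) if np.isfinite(lo) else np.nan
                per_method[m]["points"].append(pt)
                per_method[m]["covered"].append(covered)
                if return_trials:
                    records.append(
                        (si, setting.b, setting.n_units, t, m, pt, se, lo, hi, covered)
                    )

        for m in methods:
            pts = np.asarray(per_method[m]["points"], dtype=float)
            cov = np.asarray(per_method[m]["covered"], dtype=float)
            nt = pts.size
            mean_est = float(pts.mean()) if nt else np.nan
            mc_se = float(pts.std(ddof=1) / np.sqrt(nt)) if nt > 1 else np.nan
            cov_ok = cov[np.isfinite(cov)]
            coverage = float(cov_ok.mean()) if cov_ok.size else np.nan
            mc_se_cov = (
                float(np.sqrt(coverage * (1 - coverage) / cov_ok.size)) if cov_ok.size else np.nan
            )
            cells.append(
                SimulationCell(
                    method=m,
                    n_units=setting.n_units,
                    b=setting.b,
                    n_trials=nt,
                    mean_estimate=mean_est,
                    coverage=coverage,
                    mc_se_mean=mc_se,
                    mc_se_coverage=mc_se_cov,
                    n_dropped=per_method[m]["dropped"],
                )
            )
    if return_trials:
        trials = pd.DataFrame(
            records,
            columns=["setting", "b", "n_units", "trial", "method", "point", "se", "ci_low", "ci_high", "covered"],
        )
        return cells, trials
    return cells


def _pivot(cells: Sequence[SimulationCell], value: str) -> pd.DataFrame:
    rows = [(c.b, c.n_units, c.method, getattr(c, value)) for c in cells]
    df = pd.DataFrame(rows, columns=["b", "n_units", "method", value])
    if df.duplicated(["b", "n_units", "method"]).any():
        raise ValueError("duplicate (method, b, N) cells")
    table = df.pivot(index=["b", "n_units"], columns="method", values=value).sort_index()
    order = [m for m in _KNOWN_METHODS if m in table.columns]
    extra = [m for m in table.columns if m not in order]
    return table[order + extra]


def bias_table(cells: Sequence[SimulationCell]) -> pd.DataFrame:
    """Methods x (b, N) table of mean point estimates (the raw means; an
    unbiased method shows the true effect here)."""
    if not cells:
        raise ValueError("no cells")
    return _pivot(cells, "mean_estimate")


def coverage_table(cells: Sequence[SimulationCell]) -> pd.DataFrame:
    """Methods x (b, N) table of empirical 95% CI coverage."""
    if not cells:
        raise ValueError("no cells")
    return _pivot(cells, "coverage")
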