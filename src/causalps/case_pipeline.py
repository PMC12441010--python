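"""End-to-end observational case-study analysis.

The pipeline mirrors a field-study workflow for estimating the effect of
a park-level binary exposure (artificial feeding) on escape-behaviour
outcomes: standardize the continuous variables, test the
missing-completely-at-random hypothesis, multiply impute, then within
each completed dataset fit the propensity score on the designated
confounders, form overlap weights, check covariate balance, and run the
weighted outcome regression on treatment + the non-confounder covariates
(with AIC / lasso comparators over all predictors when requested). Each
per-imputation estimate carries a bootstrap standard error, and the m
results are combined by Rubin's rules.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .dgp import FieldDataset
from .estimators import estimate_aic_best, estimate_lasso, ow_weighted_regression
from .propensity import balance_report, compute_weights, fit_propensity
from .uncertainty import MCARResult, bootstrap_ci, little_mcar_test, multiple_impute, rubin_pool

__all__ = [
    "CaseStudyConfig",
    "CaseStudyResult",
    "standardize_continuous",
    "run_case_study",
    "read_field_csv",
    "write_results",
]


@dataclass
class CaseStudyConfig:
    outcome_names: tuple = ("FID", "VED")
    treatment_name: str = "Feeding"
    confounder_names: tuple = ("NH", "TN", "PGS", "P")
    covariate_names: tuple = ("TD", "DT", "CO", "PL", "NP", "RG")
    methods: tuple = ("ow",)  # subset of {'ow', 'aic', 'lasso'}
    m_imputations: int = 1000
    n_boot: int = 1000
    seed: int = 0
    level: float = 0.95
    standardize: bool = True
    standardize_outcomes: bool = True
    cluster_bootstrap: str | None = None  # e.g. 'park_id'; row-level when None
    lasso_folds: int = 10

    def __post_init__(self):
        conf, cov = set(self.confounder_names), set(self.covariate_names)
        if conf & cov:
            raise ValueError(f"confounders and covariates overlap: {sorted(conf & cov)}")
        if self.treatment_name in conf | cov:
            raise ValueError("treatment cannot appear among confounders/covariates")
        bad = set(self.methods) - {"ow", "aic", "lasso"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")

    def roles(self) -> dict:
        return {
            "treatment": self.treatment_name,
            "outcomes": list(self.outcome_names),
            "confounders": list(self.confounder_names),
            "covariates": list(self.covariate_names),
        }


@dataclass
class CaseStudyResult:
    effects: dict  # (outcome, method) -> PooledEstimate
    balance: pd.DataFrame  # covariate, smd_unweighted, smd_weighted (mean over imputations)
    mcar: MCARResult
    manifest: dict = field(default_factory=dict)


def standardize_continuous(data: FieldDataset, include_outcomes: bool = True) -> FieldDataset:
    """Center/scale every continuous column to mean 0, SD 1 (sample SD,
    denominator n-1) over its observed cells. The binary treatment and the
    park label are untouched; transform parameters are stored on the
    returned dataset for back-mapping."""
    cols = [*data.roles["confounders"], *data.roles["covariates"]]
    if include_outcomes:
        cols = [*data.roles["outcomes"], *cols]
    frame = data.frame.copy()
    transforms = dict(data.transforms)
    for c in cols:
        vals = frame[c].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size < 2:
            raise ValueError(f"column {c!r} has fewer than 2 observed values")
        sd = float(obs.std(ddof=1))
        if sd == 0:
            raise ValueError(f"zero-variance column {c!r} cannot be standardized")
        mean = float(obs.mean())
        frame[c] = (vals - mean) / sd
        transforms[c] = (mean, sd)
    out = data.copy_with(frame)
    out.transforms = transforms
    return out


def _arrays(ds: FieldDataset, outcome: str, config: CaseStudyConfig):
    f = ds.frame
    y = f[outcome].to_numpy(dtype=float)
    z = f[config.treatment_name].to_numpy(dtype=float)
    xc = f[list(config.confounder_names)].to_numpy(dtype=float)
    xo = f[list(config.covariate_names)].to_numpy(dtype=float)
    return y, z, xc, xo


def _ow_estimator(n_conf: int, conf_names):
    def est(y, z, xall, seed=None):
        fit = fit_propensity(z, xall[:, :n_conf], covariate_names=list(conf_names))
        w = compute_weights(fit, z, "overlap")
        return ow_weighted_regression(y, z, xall[:, n_conf:], w)

    return est


def _cluster_indices(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    ids = np.unique(groups)
    drawn = rng.choice(ids, size=ids.size, replace=True)
    return np.concatenate([np.nonzero(groups == g)[0] for g in drawn])


def run_case_study(data: FieldDataset, config: CaseStudyConfig) -> CaseStudyResult:
    """Run the full pipeline; see the module docstring for the stages."""
    t0 = time.time()
    stage = "standardize"
    try:
        ds = data
        if config.standardize:
            ds = standardize_continuous(ds, include_outcomes=config.standardize_outcomes)

        stage = "mcar-test"
        numeric = ds.numeric_frame()
        mcar = little_mcar_test(numeric) if numeric.isna().any().any() else MCARResult(0.0, 0, 1.0)

        stage = "imputation"
        master = np.random.SeedSequence(config.seed)
        imp_ss, boot_ss = master.spawn(2)
        imps = multiple_impute(ds, config.m_imputations, seed=imp_ss)

        stage = "estimation"
        n_conf = len(config.confounder_names)
        ow_est = _ow_estimator(n_conf, config.confounder_names)
        per = {(o, m): ([], []) for o in config.outcome_names for m in config.methods}
        balances = []
        boot_children = boot_ss.spawn(len(imps.datasets))
        for i, imp in enumerate(imps.datasets):
            rng = np.random.default_rng(boot_children[i])
            groups = (
                imp.frame[config.cluster_bootstrap].to_numpy()
                if config.cluster_bootstrap
                else None
            )
            z = imp.frame[config.treatment_name].to_numpy(dtype=float)
            xc = imp.frame[list(config.confounder_names)].to_numpy(dtype=float)
            fit = fit_propensity(z, xc, covariate_names=list(config.confounder_names))
            w = compute_weights(fit, z, "overlap")
            balances.append(balance_report(xc, z, w, names=list(config.confounder_names)).table)

            for outcome in config.outcome_names:
                y, z, xc, xo = _arrays(imp, outcome, config)
                xall = np.column_stack([xc, xo])
                x11 = np.column_stack([xc, xo])  # all candidate predictors for aic/lasso
                for m in config.methods:
                    if m == "ow":
                        est = bootstrap_ci(
                            (y, z, xall), ow_est, n_boot=config.n_boot, seed=rng, level=config.level, groups=groups
                        )
                    elif m == "aic":
                        est = bootstrap_ci(
                            (y, z, x11), "aic", n_boot=config.n_boot, seed=rng, level=config.level, groups=groups
                        )
                    else:
                        est = bootstrap_ci(
                            (y, z, x11),
                            lambda yy, zz, xx, seed=None: estimate_lasso(yy, zz, xx, n_folds=config.lasso_folds, seed=seed),
                            n_boot=config.n_boot,
                            seed=rng,
                            level=config.level,
                            groups=groups,
                        )
                    per[(outcome, m)][0].append(est.point)
                    per[(outcome, m)][1].append(est.se)

        stage = "pooling"
        effects = {}
        with warnings.catch_warnings():
            if len(imps.datasets) == 1:
                warnings.simplefilter("ignore")  # single-imputation warning is expected here
            for key, (pts, ses) in per.items():
                effects[key] = rubin_pool(pts, ses, level=config.level)
        balance = (
            pd.concat(balances)
            .groupby("covariate", sort=False)
            .mean()
            .reset_index()
        )
    except Exception as err:
        raise RuntimeError(f"case-study pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "package_version": _pkg_version,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "n_rows": int(len(data.frame)),
        "m_used": len(imps.datasets),
        "mcar": {"statistic": mcar.statistic, "df": mcar.df, "p_value": mcar.p_value},
        "smd_convention": "weighted group means; frequency-weight sample variances, pooled",
        "standardization": "sample SD (n-1) over observed cells",
        "runtime_s": round(time.time() - t0, 3),
    }
    return CaseStudyResult(effects=effects, balance=balance, mcar=mcar, manifest=manifest)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_field_csv(path, role_config) -> FieldDataset:
    """Read a delimited field table ('NA' or empty cells are missing).

    ``role_config`` is a CaseStudyConfig or a roles dict with keys
    treatment / outcomes / confounders / covariates.
    """
    roles = role_config.roles() if isinstance(role_config, CaseStudyConfig) else dict(role_config)
    frame = pd.read_csv(path, na_values=["NA"])
    needed = [roles["treatment"], *roles["outcomes"], *roles["confounders"], *roles["covariates"]]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"input file lacks required role columns: {missing}")
    treat = frame[roles["treatment"]]
    if treat.isna().any() or not treat.isin([0, 1]).all():
        raise ValueError(
            f"treatment column {roles['treatment']!r} must be coded 0/1 with no missing values "
            f"(found values like {treat.dropna().unique()[:4].tolist()})"
        )
    return FieldDataset(frame=frame, roles=roles)


def write_results(result: CaseStudyResult, out_dir) -> dict:
    """Write effects.csv, balance.csv and manifest.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "outcome": o,
            "method": m,
            "point": p.point,
            "se": p.se,
            "ci_low": p.ci_low,
            "ci_high": p.ci_high,
            "m": p.m,
        }
        for (o, m), p in result.effects.items()
    ]
    effects_path = out / "effects.csv"
    pd.DataFrame(rows).to_csv(effects_path, index=False)
    balance_path = out / "balance.csv"
    result.balance.to_csv(balance_path, index=False)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, default=str))
    return {"effects": effects_path, "balance": balance_path, "manifest": manifest_path}
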