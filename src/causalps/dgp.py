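"""Data-generating processes.

Two generators live here:

* :func:`simulate_dgp` draws from the confounded linear-model benchmark used
  throughout the Monte-Carlo study: six iid standard-normal covariates, a
  binary treatment whose assignment probability follows a (reversed) logistic
  link in four of them, and a Gaussian outcome with a homogeneous treatment
  effect.
* :func:`generate_field_like` emulates the structure of the squirrel
  field-study table (escape-behaviour outcomes FID and VED, a park-level
  binary Feeding treatment driven by four named confounders, six further
  covariates, MCAR missingness) so the case-study pipeline can be exercised
  and calibrated without the real data.

The treatment-assignment link is the *reversed* logit
``log((1-p)/p) = x . beta_prop`` — i.e. ``p = 1/(1 + exp(x . beta_prop))``.
Because the benchmark's coefficient pattern ``(0, 0, b, b, -b, -b)`` is
sign-symmetric, the reversal only flips which covariates confound positively
versus negatively; every downstream estimand is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DGPSetting",
    "SimDataset",
    "FieldDataset",
    "FIELD_CONFOUNDERS",
    "FIELD_COVARIATES",
    "FIELD_OUTCOMES",
    "simulate_dgp",
    "generate_field_like",
]

#: Default outcome coefficients of the six benchmark covariates.
DEFAULT_BETA_OUT = (1.0, 0.9, 0.9, -0.25, -0.25, 0.0)

#: Table-style roles of the synthetic field data set.
FIELD_CONFOUNDERS = ("NH", "TN", "PGS", "P")
FIELD_COVARIATES = ("TD", "DT", "CO", "PL", "NP", "RG")
FIELD_OUTCOMES = ("FID", "VED")
FIELD_TREATMENT = "Feeding"


def _beta_prop_from_b(b: float) -> np.ndarray:
    return np.array([0.0, 0.0, b, b, -b, -b], dtype=float)


@dataclass(frozen=True)
class DGPSetting:
    """Parameters of one benchmark configuration.

    Parameters
    ----------
    n_units
        Sample size N.
    b
        Confounding strength; the treatment-assignment coefficients are
        the pattern ``(0, 0, b, b, -b, -b)``.
    beta_cause
        True (homogeneous) causal effect of the treatment, default 1.0.
    beta_out
        Outcome coefficients of the six covariates.
    noise_sd
        Standard deviation of the additive Gaussian outcome noise (1.0 in
        the benchmark).
    seed
        Seed of the dataset's private random stream.
    """

    n_units: int
    b: float
    beta_cause: float = 1.0
    beta_out: tuple = DEFAULT_BETA_OUT
    noise_sd: float = 1.0
    seed: int = 0
    beta_prop: tuple = field(default=None)  # derived from b unless given

    def __post_init__(self):
        if self.n_units < 1:
            raise ValueError("n_units must be a positive integer")
        if self.beta_prop is None:
            object.__setattr__(self, "beta_prop", tuple(_beta_prop_from_b(self.b)))
        bp = np.asarray(self.beta_prop, dtype=float)
        bo = np.asarray(self.beta_out, dtype=float)
        if bp.shape != (6,) or bo.shape != (6,):
            raise ValueError("beta_prop and beta_out must have length 6")
        vals = np.concatenate([[self.b, self.beta_cause, self.noise_sd], bp, bo])
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite parameter in DGPSetting")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def with_seed(self, seed: int) -> "DGPSetting":
        return replace(self, seed=int(seed))


@dataclass
class SimDataset:
    """One simulated draw: outcome ``y``, treatment ``z`` (0/1), covariate
    matrix ``x`` (N x 6) and the true assignment probabilities ``true_ps``."""

    y: np.ndarray
    z: np.ndarray
    x: np.ndarray
    true_ps: np.ndarray

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {"Y": self.y, "Z": self.z.astype(int)}
        for j in range(self.x.shape[1]):
            cols[f"X{j + 1}"] = self.x[:, j]
        cols["true_ps"] = self.true_ps
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")


def simulate_dgp(setting: DGPSetting) -> SimDataset:
    """Draw one dataset from the confounded benchmark.

    Covariates are iid N(0,1); the assignment probability is the reversed
    logit ``p = 1/(1 + exp(x . beta_prop))``; the outcome is
    ``y = z*beta_cause + x . beta_out + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(setting.seed)
    n = setting.n_units
    x = rng.standard_normal((n, 6))
    eta = x @ np.asarray(setting.beta_prop, dtype=float)
    # reversed logit link, implemented exactly as specified
    p = 1.0 / (1.0 + np.exp(eta))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    z = (rng.random(n) < p).astype(float)
    y = (
        z * setting.beta_cause
        + x @ np.asarray(setting.beta_out, dtype=float)
        + rng.normal(0.0, setting.noise_sd, size=n)
    )
    return SimDataset(y=y, z=z, x=x, true_ps=p)


# ---------------------------------------------------------------------------
# Synthetic field data
# ---------------------------------------------------------------------------


@dataclass
class FieldDataset:
    """Case-study-shaped table plus its column-role map.

    ``frame`` holds one row per observation with columns ``park_id``, the
    binary treatment, two outcomes and ten covariates; missing cells are
    NaN. ``roles`` maps 'treatment' / 'outcomes' / 'confounders' /
    'covariates' to column names. ``transforms`` records any
    standardization applied as name -> (mean, sd) for back-mapping.
    """

    frame: pd.DataFrame
    roles: dict
    transforms: dict = field(default_factory=dict)

    def __post_init__(self):
        conf = set(self.roles["confounders"])
        cov = set(self.roles["covariates"])
        if conf & cov:
            raise ValueError(f"confounder/covariate roles overlap: {sorted(conf & cov)}")
        treat = self.roles["treatment"]
        if treat in conf | cov:
            raise ValueError("treatment cannot also be a confounder/covariate")
        needed = [treat, *self.roles["outcomes"], *conf, *cov]
        missing = [c for c in needed if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing role columns: {missing}")
        t = self.frame[treat]
        if t.isna().any() or not t.isin([0, 1]).all():
            raise ValueError(f"treatment column {treat!r} must be binary 0/1 with no missing values")
        if "park_id" in self.frame.columns:
            if self.frame.groupby("park_id")[treat].nunique().gt(1).any():
                raise ValueError("treatment must be constant within park_id")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.numeric_frame().isna()

    def numeric_frame(self) -> pd.DataFrame:
        """All analysis columns (outcomes + confounders + covariates)."""
        cols = [*self.roles["outcomes"], *self.roles["confounders"], *self.roles["covariates"]]
        return self.frame[cols]

    @property
    def treatment(self) -> np.ndarray:
        return self.frame[self.roles["treatment"]].to_numpy(dtype=float)

    def copy_with(self, frame: pd.DataFrame) -> "FieldDataset":
        return FieldDataset(frame=frame, roles=dict(self.roles), transforms=dict(self.transforms))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, na_rep="NA")


def default_field_roles() -> dict:
    return {
        "treatment": FIELD_TREATMENT,
        "outcomes": list(FIELD_OUTCOMES),
        "confounders": list(FIELD_CONFOUNDERS),
        "covariates": list(FIELD_COVARIATES),
    }


DEFAULT_FEED_COEFS = (0.8, 0.8, -0.8, 0.8)
DEFAULT_OUTCOME_COEFS: Mapping[str, float] = {
    # confounders influence the outcomes (that is what makes them confounders)
    "NH": -0.5,
    "TN": 0.4,
    "PGS": 0.4,
    "P": -0.3,
    # plain covariates: outcome-only
    "TD": 0.3,
    "DT": 0.5,
    "CO": 0.2,
    "PL": 0.0,
    "NP": -0.2,
    "RG": 0.2,
}


def generate_field_like(
    n_parks: int = 12,
    obs_per_park: int = 10,
    feed_coefs: Sequence[float] = DEFAULT_FEED_COEFS,
    outcome_coefs: Mapping[str, float] | None = None,
    effect_fid: float = -1.0,
    effect_ved: float = -1.0,
    missing_rate: float = 0.1,
    seed: int = 0,
    max_retries: int = 100,
) -> FieldDataset:
    """Generate a synthetic field-study table.

    Park-level confounders (NH, TN, PGS, P) are standard normal and shared
    by all observations in a park; Feeding is drawn once per park from a
    logistic model in the confounders; the six remaining covariates vary
    per observation. Outcomes are linear in treatment and covariates with
    unit Gaussian noise. Missingness is applied completely at random to
    outcome/covariate cells only (never the treatment or park label).
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if n_parks < 2:
        raise ValueError("n_parks must be >= 2")
    feed_coefs = np.asarray(feed_coefs, dtype=float)
    if feed_coefs.shape != (4,):
        raise ValueError("feed_coefs must have length 4 (one per confounder)")
    coefs = dict(DEFAULT_OUTCOME_COEFS)
    if outcome_coefs:
        unknown = set(outcome_coefs) - set(coefs)
        if unknown:
            raise ValueError(f"unknown outcome_coefs keys: {sorted(unknown)}")
        coefs.update(outcome_coefs)

    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        conf_park = rng.standard_normal((n_parks, 4))  # NH, TN, PGS, P
        p_feed = 1.0 / (1.0 + np.exp(-(conf_park @ feed_coefs)))
        feeding_park = (rng.random(n_parks) < p_feed).astype(int)
        if 0 < feeding_park.sum() < n_parks:
            break
    else:
        raise RuntimeError(
            f"could not draw both fed and unfed parks in {max_retries} attempts; "
            "propensity scores would be inestimable"
        )

    n = n_parks * obs_per_park
    park_id = np.repeat(np.arange(n_parks), obs_per_park)
    data = {"park_id": park_id, FIELD_TREATMENT: feeding_park[park_id]}
    for j, name in enumerate(FIELD_CONFOUNDERS):
        data[name] = conf_park[park_id, j]
    for name in FIELD_COVARIATES:
        data[name] = rng.standard_normal(n)

    lin = np.zeros(n)
    for name in (*FIELD_CONFOUNDERS, *FIELD_COVARIATES):
        lin = lin + coefs[name] * data[name]
    feed = data[FIELD_TREATMENT].astype(float)
    data["FID"] = effect_fid * feed + lin + rng.standard_normal(n)
    data["VED"] = effect_ved * feed + lin + rng.standard_normal(n)

    frame = pd.DataFrame(data)
    order = ["park_id", FIELD_TREATMENT, *FIELD_OUTCOMES, *FIELD_CONFOUNDERS, *FIELD_COVARIATES]
    frame = frame[order]
    if missing_rate > 0:
        maskable = [*FIELD_OUTCOMES, *FIELD_CONFOUNDERS, *FIELD_COVARIATES]
        holes = rng.random((n, len(maskable))) < missing_rate
        vals = frame[maskable].to_numpy()
        vals[holes] = np.nan
        frame[maskable] = vals
    return FieldDataset(frame=frame, roles=default_field_roles())
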