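"""Tests of the bootstrap, Little's MCAR test, multiple imputation and
Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from causalps.dgp import generate_field_like
from causalps.uncertainty import (
    bootstrap_ci,
    em_norm,
    little_mcar_test,
    multiple_impute,
    rubin_pool,
)


class TestBootstrap:
    def test_constant_estimator_gives_degenerate_interval(self):
        est = bootstrap_ci(np.arange(20.0), lambda y: 3.25, n_boot=50, seed=0)
        assert est.se == 0.0
        assert (est.ci_low, est.ci_high) == (3.25, 3.25)

    def test_se_of_mean_matches_closed_form(self, rng):
        y = rng.standard_normal(30) * 2.0 + 1.0
        est = bootstrap_ci(y, lambda v: float(np.mean(v)), n_boot=10_000, seed=1)
        n = len(y)
        expect = y.std(ddof=1) * np.sqrt((n - 1) / n) / np.sqrt(n)
        assert est.se == pytest.approx(expect, rel=0.05)
        assert est.point == pytest.approx(y.mean())

    def test_failure_rate_threshold(self):
        # succeeds on the original sample but fails on (essentially) every
        # bootstrap resample, which contains ties
        def flaky(y):
            if len(np.unique(y)) < len(y):
                raise ValueError("ties")
            return float(y.mean())

        with pytest.raises(RuntimeError, match="failed"):
            bootstrap_ci(np.arange(10.0), flaky, n_boot=20, seed=2)

    def test_single_class_resamples_redrawn(self, rng):
        y = rng.standard_normal(8)
        z = np.array([1, 0, 0, 0, 0, 0, 0, 0.0])  # single treated unit
        est = bootstrap_ci(
            (y, z, None),
            lambda yy, zz, xx: float(yy[zz == 1].mean() - yy[zz == 0].mean()),
            n_boot=200,
            seed=3,
        )
        assert est.meta["n_redrawn"] > 0
        assert np.isfinite(est.se)

    def test_percentile_interval_contains_point(self, rng):
        y = rng.standard_normal(50)
        est = bootstrap_ci(y, lambda v: float(np.median(v)), n_boot=500, seed=4, percentile=True)
        assert est.ci_low <= est.point <= est.ci_high


class TestEMAndLittle:
    def test_em_on_complete_data_returns_sample_moments(self, rng):
        Y = rng.standard_normal((100, 3)) @ np.diag([1.0, 2.0, 0.5])
        mu, Sigma, *_ = em_norm(Y)
        assert np.allclose(mu, Y.mean(0), atol=1e-10)
        assert np.allclose(Sigma, np.cov(Y.T, bias=True), atol=1e-8)

    def test_complete_data_statistic_zero(self, rng):
        Y = rng.standard_normal((50, 3))
        res = little_mcar_test(Y)
        assert res == (0.0, 0, 1.0)

    def test_monotone_two_pattern_closed_form_oracle(self, rng):
        """For bivariate data where x2 is missing on a tail block, the ML
        estimate has a closed form via the factored likelihood; the EM-based
        statistic must agree with direct arithmetic."""
        n, n_complete = 120, 80
        cov = np.array([[1.0, 0.6], [0.6, 1.5]])
        Y = rng.multivariate_normal([0.5, -0.2], cov, size=n)
        Y[n_complete:, 1] = np.nan

        res = little_mcar_test(Y)

        # closed-form ML: x1 marginal from all rows, x2|x1 regression from
        # complete rows (ML variances, divide by n)
        x1_all = Y[:, 0]
        mu1 = x1_all.mean()
        s11 = x1_all.var()
        xc, yc = Y[:n_complete, 0], Y[:n_complete, 1]
        beta = np.cov(xc, yc, bias=True)[0, 1] / xc.var()
        alpha = yc.mean() - beta * xc.mean()
        s_cond = np.mean((yc - alpha - beta * xc) ** 2)
        mu2 = alpha + beta * mu1
        s12 = beta * s11
        s22 = s_cond + beta**2 * s11
        mu = np.array([mu1, mu2])
        Sigma = np.array([[s11, s12], [s12, s22]])

        d2 = 0.0
        ybar_c = Y[:n_complete].mean(0)
        dev = ybar_c - mu
        d2 += n_complete * dev @ np.linalg.solve(Sigma, dev)
        ybar_m = Y[n_complete:, 0].mean()
        d2 += (n - n_complete) * (ybar_m - mu1) ** 2 / s11
        df = (2 + 1) - 2

        assert res.df == df
        assert res.statistic == pytest.approx(d2, rel=1e-4)
        assert res.p_value == pytest.approx(stats.chi2.sf(d2, df), rel=1e-3)

    def test_null_calibration_under_mcar(self):
        """Under MCAR holes the p-values are approximately uniform."""
        reject = 0
        n_rep = 500
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            A = np.array([[1.0, 0.4, 0.0], [0.4, 1.0, 0.3], [0.0, 0.3, 1.0]])
            Y = r.multivariate_normal(np.zeros(3), A, size=60)
            holes = r.random(Y.shape) < 0.2
            holes[holes.all(axis=1)] = False
            Y[holes] = np.nan
            if not np.isnan(Y).any():
                continue
            if little_mcar_test(Y).p_value < 0.05:
                reject += 1
        assert 0.03 <= reject / n_rep <= 0.08

    def test_detects_non_mcar_missingness(self, rng):
        Y = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=400)
        # delete x2 where x1 is large: decidedly not MCAR
        Y[Y[:, 0] > 0.5, 1] = np.nan
        assert little_mcar_test(Y).p_value < 1e-4


class TestMultipleImpute:
    def test_complete_data_gives_identical_copies(self, rng):
        df = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        imps = multiple_impute(df, m=4, seed=0)
        assert imps.m == 4
        for d in imps.datasets:
            pd.testing.assert_frame_equal(d, df)

    def test_observed_cells_preserved_bitwise(self, rng):
        Y = rng.standard_normal((60, 3))
        holes = rng.random(Y.shape) < 0.25
        Yp = Y.copy()
        Yp[holes] = np.nan
        df = pd.DataFrame(Yp, columns=list("abc"))
        imps = multiple_impute(df, m=5, seed=1)
        for d in imps.datasets:
            arr = d.to_numpy()
            assert np.array_equal(arr[~holes], Y[~holes])
            assert not np.isnan(arr).any()

    def test_conditional_mean_tracks_correlation(self, rng):
        """Bivariate normal with correlation 0.8: imputed x2 values follow
        the conditional regression 0.8 * x1."""
        n = 400
        Y = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=n)
        holes = rng.random(n) < 0.3
        Yp = Y.copy()
        Yp[holes, 1] = np.nan
        imps = multiple_impute(pd.DataFrame(Yp, columns=["x1", "x2"]), m=50, seed=2)
        stack_x1, stack_x2 = [], []
        for d in imps.datasets:
            stack_x1.append(d["x1"].to_numpy()[holes])
            stack_x2.append(d["x2"].to_numpy()[holes])
        x1 = np.concatenate(stack_x1)
        x2 = np.concatenate(stack_x2)
        slope = np.polyfit(x1, x2, 1)[0]
        assert slope == pytest.approx(0.8, abs=0.1)

    def test_field_dataset_roundtrip_and_reproducibility(self):
        fd = generate_field_like(n_parks=8, obs_per_park=6, missing_rate=0.15, seed=3)
        a = multiple_impute(fd, m=3, seed=42)
        b = multiple_impute(fd, m=3, seed=42)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da.frame, db.frame)
        assert all(not d.frame[d.roles["outcomes"]].isna().any().any() for d in a.datasets)

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            multiple_impute(df, m=2, seed=0)


class TestRubinPool:
    def test_identical_inputs_pass_through(self):
        p = rubin_pool([2.0, 2.0, 2.0], [0.5, 0.5, 0.5])
        assert p.point == 2.0
        assert p.se == pytest.approx(0.5)

    def test_worked_example(self):
        p = rubin_pool([1.0, 3.0], [1.0, 1.0])
        assert p.point == 2.0
        assert p.within == pytest.approx(1.0)
        assert p.between == pytest.approx(2.0)
        assert p.total_variance == pytest.approx(4.0)
        assert p.se == pytest.approx(2.0)

    def test_point_is_mean_regardless_of_ses(self, rng):
        pts = rng.standard_normal(7)
        p = rubin_pool(pts, rng.uniform(0.1, 2.0, 7))
        assert p.point == pytest.approx(pts.mean())

    def test_total_variance_monotone_in_spread(self):
        base = np.array([0.8, 1.0, 1.2])
        ses = np.ones(3)
        t_small = rubin_pool(base, ses).total_variance
        t_large = rubin_pool(1.0 + 3 * (base - 1.0), ses).total_variance
        assert t_large >= t_small

    def test_single_imputation_warns(self):
        with pytest.warns(UserWarning, match="m=1"):
            p = rubin_pool([1.5], [0.3])
        assert p.point == 1.5
        assert p.se == pytest.approx(0.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rubin_pool([1.0, 2.0], [0.1])
        with pytest.raises(ValueError):
            rubin_pool([1.0], [-0.1])
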