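"""Trend regression, the SNR statistic and whole-cube detection maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from octrend import (
    DetectConfig,
    InsufficientDataError,
    SpectralCube,
    SynthConfig,
    TrendEstimate,
    confidence_to_snr,
    detect_cell,
    detect_map,
    generate_scene,
    multivariate_trend,
    single_band_maps,
    snr,
    snr_to_confidence,
)
from octrend.synthetic import banded_noise_cov


def design_kappa(n: int) -> float:
    """Slope element of (X'X)^-1 for the centred design [1, t]."""
    t = np.arange(n, dtype=float)
    t -= t.mean()
    return 1.0 / np.dot(t, t)


def expected_snr(b, sigma_stat, n) -> float:
    """Population SNR of a planted trend under stationary noise covariance."""
    b = np.asarray(b, dtype=float)
    C = np.asarray(sigma_stat) * design_kappa(n)
    nb = np.linalg.norm(b)
    return nb**2 / np.sqrt(b @ C @ b)


class TestMultivariateTrend:
    def test_noiseless_fit_exact(self):
        t = np.arange(10.0)
        slopes = np.array([2.0, -1.0, 0.0])
        Y = 1.0 + np.outer(t, slopes)
        est = multivariate_trend(Y, t)
        np.testing.assert_allclose(est.b, slopes, atol=1e-12)
        np.testing.assert_allclose(est.C, 0.0, atol=1e-18)

    def test_single_band_matches_simple_regression(self, rng):
        t = np.arange(20.0)
        y = 0.5 * t + rng.standard_normal(20)
        est = multivariate_trend(y[:, None], t)
        ref = stats.linregress(t, y)
        assert est.b[0] == pytest.approx(ref.slope, rel=1e-12)
        assert est.stderr[0] == pytest.approx(ref.stderr, rel=1e-12)

    def test_sampling_covariance_matches_closed_form(self, rng):
        # empirical covariance of slope estimates across replicates should
        # match C = Sigma * kappa element-wise
        n, reps = 20, 5000
        Sigma = banded_noise_cov([1.0, 1.5, 2.0], corr=0.6)
        L = np.linalg.cholesky(Sigma)
        t = np.arange(float(n))
        bs = np.empty((reps, 3))
        for k in range(reps):
            Y = rng.standard_normal((n, 3)) @ L.T
            bs[k] = multivariate_trend(Y, t).b
        C_emp = np.cov(bs.T)
        C_true = Sigma * design_kappa(n)
        np.testing.assert_allclose(C_emp, C_true, rtol=0.1)

    def test_insufficient_rows_raise(self):
        with pytest.raises(InsufficientDataError):
            multivariate_trend(np.ones((2, 2)), np.arange(2.0))

    def test_constant_regressor_raises(self):
        with pytest.raises(InsufficientDataError):
            multivariate_trend(np.ones((5, 1)), design=np.ones((5, 2)))


class TestSnr:
    def test_zero_trend_is_zero(self):
        est = TrendEstimate(b=np.zeros(3), C=np.eye(3), n_effective=20)
        assert snr(est) == 0.0

    def test_identity_covariance_gives_norm(self):
        b = np.array([3.0, 4.0])
        est = TrendEstimate(b=b, C=np.eye(2), n_effective=20)
        assert snr(est) == pytest.approx(5.0)

    @pytest.mark.parametrize("rho,expected", [(0.0, np.sqrt(2)), (1.0, 1.0),
                                              (0.5, np.sqrt(2 / 1.5))])
    def test_correlated_uncertainty_quadratic_form(self, rho, expected):
        est = TrendEstimate(b=np.array([1.0, 1.0]),
                            C=np.array([[1.0, rho], [rho, 1.0]]), n_effective=20)
        assert snr(est) == pytest.approx(expected)

    def test_noiseless_sentinel_is_infinite(self):
        est = TrendEstimate(b=np.array([1.0]), C=np.zeros((1, 1)), n_effective=20)
        assert np.isposinf(snr(est))

    @given(perm_seed=st.integers(0, 100), scale=st.floats(0.01, 100.0))
    def test_invariance_under_permutation_and_rescaling(self, perm_seed, scale):
        rng = np.random.default_rng(perm_seed)
        b = rng.normal(size=4)
        A = rng.normal(size=(4, 4))
        C = A @ A.T + 0.1 * np.eye(4)
        base = snr(TrendEstimate(b=b, C=C, n_effective=20))
        p = rng.permutation(4)
        permuted = snr(TrendEstimate(b=b[p], C=C[np.ix_(p, p)], n_effective=20))
        scaled = snr(TrendEstimate(b=scale * b, C=scale**2 * C, n_effective=20))
        assert permuted == pytest.approx(base, rel=1e-10)
        assert scaled == pytest.approx(base, rel=1e-10)


class TestThresholdConfidence:
    def test_two_is_9545_percent(self):
        assert snr_to_confidence(2.0) == pytest.approx(95.45, abs=0.005)

    @pytest.mark.parametrize("th,pct", [(1.645, 90), (2.576, 99)])
    def test_alternative_thresholds(self, th, pct):
        assert round(snr_to_confidence(th)) == pct

    @given(pct=st.floats(1.0, 99.9))
    def test_round_trip(self, pct):
        assert snr_to_confidence(confidence_to_snr(pct)) == pytest.approx(pct, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            confidence_to_snr(120.0)
        with pytest.raises(ValueError):
            snr_to_confidence(-1.0)


class TestDetectCell:
    def test_noiseless_linear_input(self):
        t = np.arange(20.0)
        Y = np.outer(t, [1e-5, -2e-5])
        res = detect_cell(Y, t, DetectConfig(prewhiten=False))
        np.testing.assert_allclose(res.estimate.b, [1e-5, -2e-5], atol=1e-18)
        assert np.isposinf(res.snr)

    def test_complete_case_row_dropping(self, rng):
        t = np.arange(20.0)
        Y = rng.standard_normal((20, 3))
        Y[5, 1] = np.nan
        res = detect_cell(Y, t, DetectConfig(min_years=15))
        assert res.estimate.n_effective <= 19

    def test_too_few_years_raise(self, rng):
        Y = rng.standard_normal((10, 2))
        with pytest.raises(InsufficientDataError):
            detect_cell(Y, np.arange(10.0), DetectConfig(min_years=15))

    def test_null_calibration_matches_direct_oracle(self, rng):
        """Dual route: the detector's null exceedance rate on generator cells
        must match a direct Monte-Carlo simulation of the same statistic
        (OLS slopes + projected covariance) under the same noise covariance.
        """
        n, reps = 20, 800
        Sigma = banded_noise_cov(0.02 * np.ones(10), corr=0.9)
        L = np.linalg.cholesky(Sigma)
        t = np.arange(float(n))
        tc = t - t.mean()
        X = np.column_stack([np.ones(n), tc])
        XtXi = np.linalg.inv(X.T @ X)
        kappa = XtXi[1, 1]
        hits_oracle = 0
        for _ in range(reps):
            Y = rng.standard_normal((n, 10)) @ L.T
            beta = XtXi @ X.T @ Y
            resid = Y - X @ beta
            b = beta[1]
            C = (resid.T @ resid / (n - 2)) * kappa
            hits_oracle += np.linalg.norm(b) ** 2 / np.sqrt(b @ C @ b) > 2
        rate_oracle = hits_oracle / reps

        from octrend.synthetic import generate_cell_series
        hits_pkg = 0
        for k in range(reps):
            Y = generate_cell_series(np.zeros(10), np.zeros(10), Sigma, 0.0, n,
                                     seed=30_000 + k)
            hits_pkg += detect_cell(Y, t, DetectConfig(prewhiten=False)).snr > 2
        rate_pkg = hits_pkg / reps
        assert rate_pkg == pytest.approx(rate_oracle, abs=0.04)


class TestDetectMap:
    def test_all_masked_cube_gives_invalid_field(self):
        cube = SpectralCube(values=np.full((2, 2, 20, 3), np.nan),
                            lat=[0.0, 2.0], lon=[0.0, 2.0],
                            time=np.arange(20), band=[412.0, 443.0, 469.0])
        field = detect_map(cube)
        assert not field.valid.any()

    def test_single_band_cube_equals_univariate_path(self, small_config):
        cfg = SynthConfig(n_lat=3, n_lon=4, n_years=20, seed=3,
                          band_centers=[443.0], intercepts=[5e-3],
                          trends=[1e-4], noise_cov=[[1e-8]])
        cube = generate_scene(cfg)
        direct = detect_map(cube)
        via_bands = single_band_maps(cube)[443.0]
        np.testing.assert_allclose(direct.snr, via_bands.snr, rtol=1e-12)

    def test_mask_nesting_across_thresholds(self, small_config):
        field = detect_map(generate_scene(small_config))
        m = field.masks
        assert np.all(m[2.0] <= m[1.645])
        assert np.all(m[2.576] <= m[2.0])

    def test_planted_signal_recovery(self):
        """Cells planted at design SNR 5 are separated from null cells with
        high balanced accuracy at threshold 2."""
        n_lat, n_lon, n = 10, 20, 20
        Sigma = banded_noise_cov(0.02 * np.ones(5), corr=0.9)
        sig_stat = Sigma  # rho = 0: stationary cov = innovation cov
        u = np.ones(5) / np.sqrt(5)
        # scale ||b|| for a population SNR of 5
        scale = 5.0 * np.sqrt(u @ (sig_stat * design_kappa(n)) @ u)
        trends = np.zeros((n_lat, n_lon, 5))
        planted = np.zeros((n_lat, n_lon), dtype=bool)
        planted[:, : n_lon // 2] = True
        trends[planted] = scale * u
        cfg = SynthConfig(n_lat=n_lat, n_lon=n_lon, n_years=n, seed=17,
                          band_centers=[412.0, 443.0, 469.0, 488.0, 531.0],
                          intercepts=np.full(5, 5e-3), trends=trends,
                          noise_cov=Sigma, ar1_coeff=0.0)
        field = detect_map(generate_scene(cfg))
        detected = field.mask(2.0)
        tpr = detected[planted].mean()
        tnr = 1.0 - detected[~planted].mean()
        assert (tpr + tnr) / 2 >= 0.85

    def test_multivariate_beats_single_bands_for_spread_trend(self):
        n_lat, n_lon, n, p = 8, 16, 20, 5
        Sigma = banded_noise_cov(0.02 * np.ones(p), corr=0.9)
        u = np.ones(p) / np.sqrt(p)
        scale = 3.0 * np.sqrt(u @ (Sigma * design_kappa(n)) @ u)
        cfg = SynthConfig(n_lat=n_lat, n_lon=n_lon, n_years=n, seed=23,
                          band_centers=[412.0, 443.0, 469.0, 488.0, 531.0],
                          intercepts=np.full(p, 5e-3), trends=scale * u,
                          noise_cov=Sigma, ar1_coeff=0.0)
        cube = generate_scene(cfg)
        multi = detect_map(cube).mask(2.0).mean()
        per_band = [f.mask(2.0).mean() for f in single_band_maps(cube).values()]
        assert multi >= max(per_band) - 1e-12
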