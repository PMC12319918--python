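"""Lag-stacked design construction, ridge / measurement-error-corrected
kernel estimation, gamma parameterization, and the spatiotemporal forward
model."""

import numpy as np
import pytest

from fusnpx.config import GammaParams
from fusnpx.transfer import (
    build_design,
    fit_gamma,
    fit_spatial_sigma,
    fit_tf,
    fit_tf_cv,
    fit_tf_eiv,
    forward_model,
    predict_and_score,
)
from fusnpx.metrics import fwhm


def _convolved_pair(rng, kernel, n=170, scale=1.0):
    sr = rng.standard_normal(n) * scale
    di = np.convolve(sr, kernel, mode="full")[:n]
    return sr, di


class TestBuildDesign:
    def test_row_and_column_counts(self, rng):
        sr = rng.standard_normal(170)
        X, y = build_design([sr], [sr], lag=20)
        assert X.shape == (150, 21)
        X6, y6 = build_design([sr] * 6, [sr] * 6, lag=20)
        assert X6.shape == (900, 21)

    def test_column_j_holds_lag_j(self, rng):
        sr = rng.standard_normal(40)
        X, y = build_design([sr], [np.zeros(40)], lag=3)
        np.testing.assert_array_equal(X[:, 0], sr[3:])
        np.testing.assert_array_equal(X[:, 3], sr[:-3])

    def test_constant_input_is_rank_one(self):
        X, _ = build_design([np.full(60, 4.0)], [np.zeros(60)], lag=5)
        assert np.linalg.matrix_rank(X) == 1

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            build_design([np.zeros(10)], [np.zeros(10)], lag=20)


class TestFitTF:
    def test_known_kernel_recovered_noiselessly(self, rng):
        kernel = GammaParams(1.0, 3.0, 0.4, 0.0).sample(21, 0.2)
        sr, di = _convolved_pair(rng, kernel)
        X, y = build_design([sr], [di], lag=20)
        tf = fit_tf(X, y, ridge_lambda=1e-8)
        assert np.max(np.abs(tf.coeffs - kernel)) < 1e-6

    def test_zero_output_gives_zero_kernel(self, rng):
        sr = rng.standard_normal(170)
        X, y = build_design([sr], [np.zeros(170)], lag=20)
        tf = fit_tf(X, y, ridge_lambda=1.0)
        np.testing.assert_allclose(tf.coeffs, 0.0, atol=1e-10)

    def test_infinite_shrinkage_limit(self, rng):
        kernel = np.ones(21)
        sr, di = _convolved_pair(rng, kernel)
        X, y = build_design([sr], [di], lag=20)
        tf = fit_tf(X, y, ridge_lambda=1e12)
        assert np.max(np.abs(tf.coeffs)) < 1e-3

    def test_lambda_zero_equals_ols(self, rng):
        X = rng.standard_normal((200, 21))
        y = rng.standard_normal(200)
        tf = fit_tf(X, y, ridge_lambda=0.0)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        assert np.max(np.abs(tf.coeffs - beta)) < 1e-8

    def test_singular_design_with_zero_lambda_raises(self):
        X, y = build_design([np.full(60, 2.0)], [np.zeros(60)], lag=5)
        with pytest.raises(np.linalg.LinAlgError, match="ridge_lambda"):
            fit_tf(X, y, ridge_lambda=0.0)

    def test_cv_picks_small_penalty_on_clean_data(self, rng):
        kernel = GammaParams(1.0, 3.0, 0.4, 0.0).sample(21, 0.2)
        pairs = [_convolved_pair(rng, kernel, scale=s) for s in (1, 2, 3)]
        tf = fit_tf_cv([p[0] for p in pairs], [p[1] for p in pairs], lag=20)
        assert np.max(np.abs(tf.coeffs - kernel)) < 1e-3

    def test_eiv_with_zero_variance_matches_plain_ridge(self, rng):
        kernel = GammaParams(1.0, 3.0, 0.4, 0.0).sample(21, 0.2)
        sr, di = _convolved_pair(rng, kernel)
        lam = 5.0
        tf_eiv = fit_tf_eiv([sr], [di], [np.zeros_like(sr)], lag=20,
                            grid=np.array([lam]))
        X, y = build_design([sr], [di], lag=20)
        tf = fit_tf(X, y, ridge_lambda=lam)
        np.testing.assert_allclose(tf_eiv.coeffs, tf.coeffs, atol=1e-6)

    def test_eiv_corrects_attenuation_from_input_noise(self, rng):
        # noisy regressors attenuate the plain estimate; the corrected fit
        # recovers the kernel's width
        kernel = GammaParams(1.0, 6.62156, 0.142309, 0.0).sample(21, 0.2)
        true_fwhm = fwhm(kernel, 0.2)
        est_plain, est_eiv = [], []
        for _ in range(5):
            srs, dis, vars_ = [], [], []
            for scale in (1.0, 2.0, 3.0):  # conditions for cross-validation
                clean = scale * np.repeat(rng.uniform(0, 3, 34), 5)
                dis.append(np.convolve(clean, kernel, "full")[:170])
                srs.append(clean + rng.standard_normal(170) * 1.5)
                vars_.append(np.full(170, 1.5**2))
            X, y = build_design(srs, dis, lag=20)
            est_plain.append(fwhm(fit_tf(X, y, 1e-3).coeffs, 0.2))
            est_eiv.append(
                fwhm(fit_tf_eiv(srs, dis, vars_, lag=20).coeffs, 0.2)
            )
        assert abs(np.mean(est_eiv) - true_fwhm) <= abs(np.mean(est_plain) - true_fwhm)
        assert np.mean(est_eiv) == pytest.approx(true_fwhm, rel=0.35)


class TestFitGamma:
    def test_exact_gamma_taps_recovered(self):
        true = GammaParams(1.0, 3.0, 0.4, 0.0)
        from fusnpx.transfer import TransferFunction

        tf = TransferFunction(coeffs=true.sample(21, 0.2))
        est, rms = fit_gamma(tf)
        assert rms < 1e-8
        assert est.shape == pytest.approx(true.shape, rel=0.01)
        assert est.scale_s == pytest.approx(true.scale_s, rel=0.01)
        assert est.amplitude == pytest.approx(true.amplitude, rel=0.01)
        # analytic peak of the fitted form
        assert est.time_to_peak_s == pytest.approx(0.8, rel=0.01)

    def test_flat_kernel_raises(self):
        from fusnpx.transfer import TransferFunction

        with pytest.raises(ValueError):
            fit_gamma(TransferFunction(coeffs=np.ones(21)))

    def test_negative_kernel_raises(self):
        from fusnpx.transfer import TransferFunction

        with pytest.raises(ValueError):
            fit_gamma(TransferFunction(coeffs=-np.abs(np.random.default_rng(0).standard_normal(21))))


class TestForwardModel:
    def test_zero_input_zero_output(self):
        out = forward_model(np.zeros((30, 170)), 0.15, GammaParams())
        np.testing.assert_allclose(out, 0.0)

    def test_identity_kernels_are_identity(self, rng):
        field = rng.standard_normal((30, 170))
        out = forward_model(field, 0.0, np.array([1.0]))
        np.testing.assert_allclose(out, field, atol=1e-12)

    def test_spatial_impulse_fwhm_matches_gaussian(self):
        field = np.zeros((81, 3))
        field[40, :] = 1.0
        out = forward_model(field, 0.15, np.array([1.0]), pitch_mm=0.1)
        width = fwhm(out[:, 0], step=0.1)
        assert abs(width - 2.3548 * 0.15) <= 0.1  # within one 0.1-mm bin

    def test_linearity_and_translation_equivariance(self, rng):
        gamma = GammaParams(1.0, 3.0, 0.4, 0.0)
        a = np.zeros((60, 40))
        a[20, 5] = 1.0
        out_a = forward_model(a, 0.15, gamma)
        assert np.max(np.abs(forward_model(2 * a, 0.15, gamma) - 2 * out_a)) < 1e-12
        b = np.roll(a, 7, axis=0)
        np.testing.assert_allclose(
            forward_model(b, 0.15, gamma)[10:50], np.roll(out_a, 7, axis=0)[10:50],
            atol=1e-12,
        )

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            forward_model(np.zeros((5, 5)), -0.1, GammaParams())


class TestPredictAndScore:
    def test_self_generated_data_scores_one(self, rng):
        from fusnpx.transfer import TransferFunction

        kernel = GammaParams(1.0, 3.0, 0.4, 0.0).sample(21, 0.2)
        tf = TransferFunction(coeffs=kernel)
        sr = rng.standard_normal(170)
        di = np.convolve(sr, kernel, "full")[:170]
        _, r2 = predict_and_score(tf, sr, di)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_kernel_floors_at_zero(self, rng):
        from fusnpx.transfer import TransferFunction

        tf = TransferFunction(coeffs=np.zeros(21))
        sr = rng.standard_normal(170)
        di = rng.standard_normal(170) + 5
        _, r2 = predict_and_score(tf, sr, di)
        assert r2 == 0.0

    def test_r2_decreases_with_noise(self, rng):
        from fusnpx.transfer import TransferFunction

        kernel = GammaParams(1.0, 3.0, 0.4, 0.0).sample(21, 0.2)
        tf = TransferFunction(coeffs=kernel)
        sr = np.repeat(rng.uniform(0, 3, 34), 5)
        di = np.convolve(sr, kernel, "full")[:170]
        r2s = []
        for noise in (0.1, 1.0, 5.0):
            noisy = di + rng.standard_normal(170) * noise * di.std()
            _, r2 = predict_and_score(tf, sr, noisy)
            r2s.append(r2)
        assert r2s[0] > r2s[1] > r2s[2]


class TestFitSpatialSigma:
    def test_noiseless_gaussian_profile_recovery(self):
        x = np.arange(60) * 0.1
        sr = np.exp(-0.5 * ((x - 3.0) / 0.45) ** 2)
        di = forward_model(sr[:, None], 0.15, np.array([1.0]))[:, 0]
        est = fit_spatial_sigma(sr, 3.0 * di)
        assert est == pytest.approx(0.15, abs=0.01)

    def test_variance_correction_reduces_widening_bias(self, rng):
        x = np.arange(60) * 0.1
        sr_true = np.exp(-0.5 * ((x - 3.0) / 0.45) ** 2)
        di = forward_model(sr_true[:, None], 0.15, np.array([1.0]))[:, 0]
        plain, corrected = [], []
        for _ in range(20):
            noisy = sr_true + rng.standard_normal(60) * 0.05
            var = np.full(60, 0.05**2)
            plain.append(fit_spatial_sigma(noisy, di))
            corrected.append(fit_spatial_sigma(noisy, di, input_var=var))
        assert abs(np.mean(corrected) - 0.15) < abs(np.mean(plain) - 0.15)

    def test_profiles_without_peak_rejected(self):
        with pytest.raises(ValueError):
            fit_spatial_sigma(np.zeros(30), np.zeros(30))
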