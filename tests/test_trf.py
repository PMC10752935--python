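"""Boosting TRF estimation: basis, recovery oracles, invariances, accuracy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtrf.predictors import Predictor
from hgtrf.synth import SourceRecording, SourceSpace, make_kernel, simulate_recording
from hgtrf.trf import (
    AccuracyMap,
    boost_trf,
    build_basis,
    predict_response,
    prediction_accuracy,
    smooth_accuracy,
    trf_amplitude,
)


class TestBuildBasis:
    def test_default_grid_is_125_lags_half_open(self, basis):
        assert basis.n_lags == 125
        assert basis.lag_grid_ms[0] == -40.0
        assert basis.lag_grid_ms[-1] == 208.0

    def test_single_sample_width_reduces_to_identity(self):
        b = build_basis(width_ms=2.0)  # one sample period at 500 Hz
        assert np.array_equal(b.matrix, np.eye(b.n_lags))

    def test_every_lag_covered_and_zero_coefs_give_zero_kernel(self, basis):
        assert np.all(basis.matrix.sum(axis=0) > 0)
        assert np.allclose(np.zeros(basis.n_windows) @ basis.matrix, 0.0)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            build_basis(tmin_ms=100, tmax_ms=0)


@pytest.fixture(scope="module")
def recovery_setup(basis, band_predictor):
    x = band_predictor(1, n=9000)
    kernel = make_kernel(basis.lag_grid_ms, 40.0, 5.0, 1.0, n_voxels=2, seed=2)
    clean = simulate_recording([x], kernel, [1.0], 0.0, seed=3)
    return x, kernel, clean


class TestBoostTRF:
    def test_noise_free_kernel_recovery(self, basis, recovery_setup):
        x, kernel, clean = recovery_setup
        fit = boost_trf([x], clean, basis)
        amp = trf_amplitude(fit).mean(axis=0)[0]
        assert abs(basis.lag_grid_ms[amp.argmax()] - 40.0) <= 4.0
        for v in range(2):
            r = np.corrcoef(fit.kernels[v, 0].ravel(), kernel.vectors[v, 0].ravel())[0, 1]
            assert r >= 0.95

    def test_pure_noise_response_yields_near_zero_kernels(self, basis, band_predictor):
        x = band_predictor(4, n=1000)
        kernel = make_kernel(basis.lag_grid_ms, n_voxels=1, seed=5)
        rec = simulate_recording([x], kernel, [0.0], 1.0, seed=6)
        fit = boost_trf([x], rec, basis)
        kernel_energy = float((fit.kernels**2).sum())
        response_energy = float((rec.data**2).mean() * 3)
        assert kernel_energy < 0.05 * response_energy

    def test_joint_estimation_competition(self, basis, band_predictor):
        rng = np.random.default_rng(7)
        za = rng.normal(size=9000)
        zb = 0.3 * za + np.sqrt(1 - 0.09) * rng.normal(size=9000)
        from hgtrf.predictors import highgamma_bandpass, standardize

        xa = Predictor(standardize(highgamma_bandpass(za, 500))[0], 500, "carrier", "a")
        xb = Predictor(standardize(highgamma_bandpass(zb, 500))[0], 500, "carrier", "b")
        kernel = make_kernel(basis.lag_grid_ms, n_voxels=1, n_predictors=2, seed=8)
        kernel.vectors[:, 1] = 0.0  # only predictor a drives the response
        rec = simulate_recording([xa, xb], kernel, [1.0, 1.0], 1.0, seed=9)
        fit = boost_trf([xa, xb], rec, basis)
        e_a = (fit.kernels[:, 0] ** 2).sum()
        e_b = (fit.kernels[:, 1] ** 2).sum()
        assert e_a >= 10 * e_b

    def test_predictor_order_invariance_bit_identical(self, basis, band_predictor):
        xa, xb = band_predictor(10, n=4000, label="a"), band_predictor(11, n=4000, label="b")
        kernel = make_kernel(basis.lag_grid_ms, n_voxels=1, n_predictors=2, seed=12)
        rec = simulate_recording([xa, xb], kernel, [1.0, 0.5], 0.5, seed=13)
        fit_ab = boost_trf([xa, xb], rec, basis)
        fit_ba = boost_trf([xb, xa], rec, basis)
        assert np.array_equal(fit_ab.kernels[:, 0], fit_ba.kernels[:, 1])
        assert np.array_equal(fit_ab.kernels[:, 1], fit_ba.kernels[:, 0])

    def test_fold_kernels_agree_on_clean_data(self, basis, recovery_setup):
        x, _, clean = recovery_setup
        fit = boost_trf([x], clean, basis)
        flat = fit.fold_kernels[:, 0, 0].reshape(fit.fold_count, -1)
        for i in range(fit.fold_count):
            for j in range(i + 1, fit.fold_count):
                assert np.corrcoef(flat[i], flat[j])[0, 1] >= 0.9

    def test_no_isolated_single_sample_spikes(self, basis, recovery_setup):
        # overlapping windows guarantee every nonzero sample has a nonzero neighbor
        x, _, clean = recovery_setup
        fit = boost_trf([x], clean, basis)
        for series in fit.kernels.reshape(-1, basis.n_lags):
            nz = np.flatnonzero(np.abs(series) > 0)
            for i in nz:
                neighbors = series[max(0, i - 1) : i + 2]
                assert np.count_nonzero(neighbors) >= 2 or nz.size == 0

    def test_zero_variance_component_flagged(self, basis, band_predictor):
        x = band_predictor(14, n=2000)
        data = np.zeros((1, 3, 2000))
        data[0, 0] = np.random.default_rng(15).normal(size=2000)
        rec = SourceRecording(data, 500.0, SourceSpace(np.zeros((1, 3))[0:1], 7.0))
        fit = boost_trf([x], rec, basis)
        assert fit.degenerate_channels[0, 1] and fit.degenerate_channels[0, 2]
        assert np.all(fit.kernels[0, 0, 1:] == 0.0)

    def test_length_mismatch_rejected(self, basis, band_predictor):
        x = band_predictor(16, n=1000)
        rec = simulate_recording([band_predictor(17, n=900)],
                                 make_kernel(basis.lag_grid_ms, seed=18), [0.0], 1.0)
        with pytest.raises(ValueError, match="length"):
            boost_trf([x], rec, basis)


class TestPredictResponse:
    def test_zero_kernels_zero_prediction(self, basis, band_predictor):
        x = band_predictor(20, n=1500)
        rec = simulate_recording([x], make_kernel(basis.lag_grid_ms, seed=21), [0.0], 1.0, seed=22)
        fit = boost_trf([x], rec, basis)
        fit.kernels[:] = 0.0
        pred = predict_response(fit, [x])
        assert np.allclose(pred.data, 0.0)

    def test_linearity_of_prediction(self, basis, band_predictor):
        x = band_predictor(23, n=1500)
        rec = simulate_recording([x], make_kernel(basis.lag_grid_ms, n_voxels=1, seed=24),
                                 [1.0], 0.5, seed=25)
        fit = boost_trf([x], rec, basis)
        pred1 = predict_response(fit, [x]).data
        fit.kernels = 2.0 * fit.kernels
        assert np.allclose(predict_response(fit, [x]).data, 2.0 * pred1)


class TestPredictionAccuracy:
    def test_noise_free_fit_accuracy_near_one(self, basis, recovery_setup):
        x, _, clean = recovery_setup
        fit = boost_trf([x], clean, basis)
        acc = prediction_accuracy(fit, [x], clean)
        assert np.all(acc.values >= 0.99)

    def test_zero_kernel_accuracy_defined_as_zero(self, basis, recovery_setup):
        x, _, clean = recovery_setup
        fit = boost_trf([x], clean, basis)
        fit.kernels[:] = 0.0
        fit.fold_kernels[:] = 0.0
        acc = prediction_accuracy(fit, [x], clean)
        assert np.all(acc.values == 0.0)

    def test_anti_correlated_prediction_gives_minus_one(self, basis, recovery_setup):
        x, _, clean = recovery_setup
        fit = boost_trf([x], clean, basis)
        fit.fold_kernels = -fit.fold_kernels
        acc = prediction_accuracy(fit, [x], clean)
        assert np.all(acc.values <= -0.99)


class TestTRFAmplitude:
    def test_pythagorean_triple(self, basis):
        kernels = np.zeros((1, 1, 3, basis.n_lags))
        kernels[0, 0, :, 10] = [3.0, 4.0, 0.0]
        amp = trf_amplitude(kernels)
        assert amp[0, 0, 10] == pytest.approx(5.0)
        assert np.all(amp[0, 0, :10] == 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        kernels = rng.normal(size=(2, 1, 3, 8))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = np.einsum("ij,vpjl->vpil", q, kernels)
        assert np.allclose(trf_amplitude(rotated), trf_amplitude(kernels))


class TestSmoothAccuracy:
    def test_constant_map_unchanged(self):
        ss = SourceSpace.grid((3, 3, 2))
        acc = AccuracyMap(np.full(18, 0.7))
        out = smooth_accuracy(acc, ss, 5.0)
        assert np.allclose(out.values, 0.7)

    def test_zero_sd_is_identity(self):
        ss = SourceSpace.grid((2, 2, 1))
        values = np.arange(4.0)
        out = smooth_accuracy(AccuracyMap(values), ss, 0.0)
        assert np.array_equal(out.values, values)

    def test_single_voxel_spreads_by_gaussian_distance_weights(self):
        ss = SourceSpace.grid((3, 1, 1), 7.0)
        values = np.array([0.0, 1.0, 0.0])
        out = smooth_accuracy(AccuracyMap(values), ss, 5.0)
        d2 = ((ss.voxel_coords_mm - ss.voxel_coords_mm[1]) ** 2).sum(axis=1)
        w = np.exp(-0.5 * d2 / 25.0)
        w_norm = np.array([
            w[i] / np.exp(-0.5 * ((ss.voxel_coords_mm[i] - ss.voxel_coords_mm) ** 2
                                  ).sum(axis=1) / 25.0).sum()
            for i in range(3)
        ])
        assert np.allclose(out.values, w_norm)
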