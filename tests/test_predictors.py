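"""Predictor extraction: filter specs, spectral physics, F0 tracking."""

import numpy as np
import pytest

from hgtrf.predictors import (
    Predictor,
    auditory_spectrogram,
    carrier_predictor,
    concatenate_predictors,
    envelope_modulations_predictor,
    estimate_f0,
    highgamma_bandpass,
    resample_antialias,
    standardize,
)
from hgtrf.synth import StimulusSpec, generate_stimulus


def sine(freq, rate, dur=4.0):
    return np.sin(2 * np.pi * freq * np.arange(int(dur * rate)) / rate)


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


def trim(x, frac=0.1):
    n = int(len(x) * frac)
    return x[n:-n]


class TestResampleAntialias:
    def test_dc_passband_gain_unity(self):
        out = resample_antialias(np.ones(44100), 22050, 500)
        assert out.size == 1000
        assert np.allclose(trim(out), 1.0, atol=0.01)  # within 0.1 dB

    @pytest.mark.parametrize("freq, min_ratio, max_ratio", [
        (100.0, 0.99, 1.01),        # passband: amplitude within 1%
        (300.0, 0.0, 0.01),         # stopband: >= 40 dB down
    ])
    def test_sinusoid_amplitudes(self, freq, min_ratio, max_ratio):
        out = resample_antialias(sine(freq, 22050), 22050, 500)
        ratio = rms(trim(out)) / rms(sine(freq, 22050))
        assert min_ratio <= ratio <= max_ratio

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_antialias(np.zeros(100), 500, 1000)


class TestHighgammaBandpass:
    @pytest.mark.parametrize("freq, lo, hi", [
        (100.0, 10 ** (-0.5 / 20), 10 ** (0.5 / 20)),  # passband within 0.5 dB
        (50.0, 0.0, 0.01),                              # >= 40 dB attenuation
        (220.0, 0.0, 0.01),
    ])
    def test_magnitude_response(self, freq, lo, hi):
        out = highgamma_bandpass(sine(freq, 500), 500)
        ratio = rms(trim(out)) / rms(sine(freq, 500))
        assert lo <= ratio <= hi

    def test_zero_in_zero_out_same_length(self):
        z = np.zeros(777)
        out = highgamma_bandpass(z, 500)
        assert out.shape == z.shape and np.allclose(out, 0.0)

    def test_zero_phase_symmetric_pulse_stays_symmetric(self):
        # no net group delay: processing a symmetric pulse must not shift it
        n = 2001
        x = np.zeros(n)
        x[n // 2] = 1.0
        out = highgamma_bandpass(x, 500)
        assert np.allclose(out, out[::-1], atol=1e-9)
        assert np.abs(out).argmax() == n // 2


class TestStandardize:
    def test_mean_zero_sd_one(self):
        out, flag = standardize(np.array([1.0, 2.0, 3.0]))
        assert not flag
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_degenerate(self):
        out, flag = standardize(np.full(100, 7.0))
        assert flag and np.all(out == 0.0)


@pytest.fixture(scope="module")
def harmonic_95():
    return generate_stimulus(
        StimulusSpec(duration_s=6.0, f0_mean=95.0, f0_sd=0.0, voiced_fraction=1.0,
                     phase_jitter_sd=0.0, seed=0)
    )


def spectral_peak(pred: Predictor) -> float:
    mag = np.abs(np.fft.rfft(pred.values * np.hanning(pred.values.size)))
    return float(np.fft.rfftfreq(pred.values.size, 1.0 / pred.rate)[mag.argmax()])


class TestCarrierPredictor:
    def test_spectral_peak_at_f0(self, harmonic_95):
        pred = carrier_predictor(harmonic_95)
        assert pred.kind == "carrier"
        assert pred.rate == 500.0
        assert spectral_peak(pred) == pytest.approx(95.0, abs=1.0)

    def test_silence_degenerate(self):
        pred = carrier_predictor(np.zeros(44100), rate=22050)
        assert pred.degenerate and np.all(pred.values == 0.0)

    def test_deterministic(self, harmonic_95):
        a = carrier_predictor(harmonic_95)
        b = carrier_predictor(harmonic_95)
        assert np.array_equal(a.values, b.values)


class TestAuditorySpectrogram:
    def test_tone_energy_peaks_in_nearest_bin(self):
        spec = auditory_spectrogram(sine(1000.0, 16000), rate=16000)
        energy = (spec.envelopes**2).mean(axis=1)
        best = int(energy.argmax())
        nearest = int(np.abs(spec.bins_hz - 1000.0).argmin())
        # constant-Q bank: absolute bandwidth grows with cf, so the peak may
        # land one bin above the nearest center frequency
        assert abs(best - nearest) <= 1

    def test_silence_gives_zero_envelopes(self):
        spec = auditory_spectrogram(np.zeros(16000), rate=16000)
        assert np.allclose(spec.envelopes, 0.0)
        assert np.all(spec.envelopes >= 0.0)

    def test_log_spacing_constant_ratio(self):
        spec = auditory_spectrogram(np.zeros(16000), rate=16000)
        ratios = spec.bins_hz[1:] / spec.bins_hz[:-1]
        assert np.allclose(ratios, 2.0 ** (1.0 / 24.0))

    def test_filterbank_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            auditory_spectrogram(np.zeros(8000), rate=8000)


class TestEnvelopeModulationsPredictor:
    def test_harmonic_complex_modulates_at_f0(self, harmonic_95):
        pred = envelope_modulations_predictor(harmonic_95)
        assert pred.kind == "envelope_modulations"
        assert spectral_peak(pred) == pytest.approx(95.0, abs=2.0)

    def test_unmodulated_tone_band_power_below_1pct_of_harmonic(self, harmonic_95):
        def band_power(wave, rate):
            spec = auditory_spectrogram(wave, rate=rate)
            sel = (spec.bins_hz >= 300) & (spec.bins_hz <= 4000)
            mod = highgamma_bandpass(spec.envelopes[sel], spec.frame_rate)
            return float((mod.mean(axis=0) ** 2).mean())

        p_harm = band_power(harmonic_95.waveform, 16000)
        p_tone = band_power(sine(1000.0, 16000, dur=6.0), 16000)
        assert p_tone < 0.01 * p_harm

    def test_silence_degenerate(self):
        pred = envelope_modulations_predictor(np.zeros(32000), rate=16000)
        assert pred.degenerate and np.all(pred.values == 0.0)

    def test_empty_band_rejected(self, harmonic_95):
        with pytest.raises(ValueError, match="bins"):
            envelope_modulations_predictor(harmonic_95, band_lo=7300, band_hi=7400)


class TestConcatenatePredictors:
    def test_single_identity_and_double_length(self, band_predictor):
        p = band_predictor(0, n=1000)
        assert np.array_equal(concatenate_predictors([p]).values, p.values)
        two = concatenate_predictors([p, p])
        assert two.n_samples == 2000
        assert two.block_lengths == (1000, 1000)

    def test_order_recorded_and_reversible(self, band_predictor):
        a, b = band_predictor(1, n=500, label="a"), band_predictor(2, n=700, label="b")
        ab = concatenate_predictors([a, b])
        ba = concatenate_predictors([b, a])
        assert ab.block_lengths == (500, 700) and ba.block_lengths == (700, 500)
        assert np.array_equal(ab.values[:500], ba.values[700:])

    def test_kind_mismatch_rejected(self, band_predictor):
        p = band_predictor(3, n=500)
        q = Predictor(p.values.copy(), p.rate, "envelope_modulations")
        with pytest.raises(ValueError):
            concatenate_predictors([p, q])


class TestEstimateF0:
    @pytest.mark.parametrize("f0, n_harm", [(95.0, 40), (168.0, 23)])
    def test_constant_f0_recovered_within_1hz(self, f0, n_harm):
        stim = generate_stimulus(
            StimulusSpec(duration_s=4.0, f0_mean=f0, f0_sd=0.0, n_harmonics=n_harm,
                         phase_jitter_sd=0.0, seed=1)
        )
        summary = estimate_f0(stim)
        assert summary.mean_f0 == pytest.approx(f0, abs=1.0)
        assert summary.sd_f0 < 1.0
        assert summary.voiced_fraction > 0.5

    def test_white_noise_mostly_unvoiced(self):
        noise = np.random.default_rng(0).normal(size=48000)
        summary = estimate_f0(noise, rate=16000)
        assert summary.voiced_fraction < 0.2

    def test_silence_has_no_voiced_frames(self):
        summary = estimate_f0(np.zeros(16000), rate=16000)
        assert summary.voiced_fraction == 0.0
        assert np.isnan(summary.mean_f0)
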