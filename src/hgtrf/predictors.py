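"""Stimulus predictors for high-gamma response modeling.

Two stimulus representations drive the encoding models:

* the **carrier** predictor — the waveform itself, resampled and bandpassed to
  70–200 Hz, capturing temporal fine structure (the fundamental frequency of
  voiced speech lies directly in this band for typical male voices);
* the **envelope modulations** predictor — the average across 300–4,000 Hz
  auditory-spectrogram bands of each band's envelope bandpassed to 70–200 Hz,
  capturing F0-rate amplitude modulation of the harmonics.

Both are standardized (zero mean, unit sd) single time series at the response
sampling rate (500 Hz by default).  All filtering is linear-phase FIR applied
with group-delay compensation, so predictor processing introduces no net delay
and response-function latencies remain interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

HIGH_GAMMA_BAND = (70.0, 200.0)
DEFAULT_TRANSITION_HZ = 5.0
DEFAULT_RESPONSE_RATE = 500.0

__all__ = [
    "Predictor",
    "AuditorySpectrogram",
    "F0Summary",
    "resample_antialias",
    "highgamma_bandpass",
    "standardize",
    "carrier_predictor",
    "auditory_spectrogram",
    "envelope_modulations_predictor",
    "concatenate_predictors",
    "estimate_f0",
]


@dataclass
class Predictor:
    """A standardized stimulus feature time series, the x(t) of the TRF model."""

    values: np.ndarray
    rate: float
    kind: str  # "carrier" | "envelope_modulations"
    source_label: str = ""
    degenerate: bool = False
    block_lengths: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("predictor values must be one-dimensional")
        if not self.block_lengths:
            self.block_lengths = (self.values.size,)

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass
class AuditorySpectrogram:
    """Per-band envelopes from a simplified cochlear filterbank."""

    bins_hz: np.ndarray          # center frequencies, strictly increasing
    envelopes: np.ndarray        # (n_bins, n_frames), non-negative
    frame_rate: float


@dataclass
class F0Summary:
    mean_f0: float
    sd_f0: float
    voiced_fraction: float

    @property
    def defined(self) -> bool:
        return self.voiced_fraction > 0


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def _fir_lowpass(rate: float, cutoff: float, transition: float) -> np.ndarray:
    # Hamming-window FIR: transition width ~ 3.3 / numtaps (normalized)
    numtaps = _odd(int(np.ceil(3.3 * rate / transition)))
    return signal.firwin(numtaps, cutoff + transition / 2.0, fs=rate)


def _fir_bandpass(rate: float, lo: float, hi: float, transition: float) -> np.ndarray:
    numtaps = _odd(int(np.ceil(3.3 * rate / transition)))
    edges = [lo - transition / 2.0, hi + transition / 2.0]
    if edges[0] <= 0 or edges[1] >= rate / 2.0:
        raise ValueError(
            f"bandpass edges {edges} do not fit below Nyquist ({rate / 2.0} Hz)"
        )
    return signal.firwin(numtaps, edges, pass_zero=False, fs=rate)


def _zero_phase(x: np.ndarray, taps: np.ndarray, axis: int = -1) -> np.ndarray:
    """Apply a linear-phase (symmetric) FIR with group-delay compensation.

    'same'-mode convolution with an odd-length symmetric kernel is exactly the
    zero-phase application: output length equals input length and a symmetric
    input pulse stays symmetric.
    """
    shape = [1] * x.ndim
    shape[axis] = taps.size
    return signal.fftconvolve(x, taps.reshape(shape), mode="same", axes=axis)


def resample_antialias(
    waveform: np.ndarray,
    from_rate: float,
    to_rate: float,
    cutoff: float = 200.0,
    transition: float = DEFAULT_TRANSITION_HZ,
) -> np.ndarray:
    """Lowpass-protected resampling to a lower rate.

    A linear-phase FIR prefilter with ``cutoff`` Hz passband edge and a
    ``transition`` Hz transition band is applied with group-delay compensation,
    then the signal is resampled onto a uniform grid of
    ``round(n * to_rate / from_rate)`` samples.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if to_rate >= from_rate:
        raise ValueError("resample_antialias requires to_rate < from_rate")
    if cutoff + transition / 2.0 >= to_rate / 2.0:
        warnings.warn(
            "anti-aliasing passband extends beyond the output Nyquist margin",
            stacklevel=2,
        )
    y = _zero_phase(x, _fir_lowpass(from_rate, cutoff, transition))
    n_out = int(round(x.shape[-1] * to_rate / from_rate))
    # the prefilter confines energy far below the original Nyquist, so linear
    # interpolation onto the target grid adds negligible distortion
    t_out = np.arange(n_out) * (from_rate / to_rate)
    return np.interp(t_out, np.arange(x.shape[-1], dtype=np.float64), y)


def highgamma_bandpass(
    series: np.ndarray,
    rate: float,
    band: tuple[float, float] = HIGH_GAMMA_BAND,
    transition: float = DEFAULT_TRANSITION_HZ,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase 70–200 Hz FIR bandpass (5 Hz transition bands)."""
    if rate < 2.0 * (band[1] + transition):
        warnings.warn("sampling rate leaves little margin above the passband", stacklevel=2)
    taps = _fir_bandpass(rate, band[0], band[1], transition)
    return _zero_phase(np.asarray(series, dtype=np.float64), taps, axis=axis)


def standardize(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """(x - mean) / sd; a (numerically) constant series maps to zeros.

    Returns the standardized series and a degenerate flag (True when the sd
    fell below 1e-12 * max(1, |mean|) and the zero rule applied).
    """
    x = np.asarray(series, dtype=np.float64)
    mean = float(x.mean())
    sd = float(x.std())
    if sd < 1e-12 * max(1.0, abs(mean)):
        return np.zeros_like(x), True
    return (x - mean) / sd, False


def _waveform_and_rate(stimulus, rate: float | None) -> tuple[np.ndarray, float]:
    if hasattr(stimulus, "waveform"):
        return np.asarray(stimulus.waveform, dtype=np.float64), float(
            stimulus.spec.audio_rate
        )
    if rate is None:
        raise ValueError("a raw waveform needs an explicit sampling rate")
    return np.asarray(stimulus, dtype=np.float64), float(rate)


def carrier_predictor(
    stimulus,
    rate: float | None = None,
    target_rate: float = DEFAULT_RESPONSE_RATE,
    source_label: str = "",
) -> Predictor:
    """Carrier (temporal fine structure) predictor.

    Resample the waveform to ``target_rate`` (anti-aliasing FIR, 200 Hz cutoff,
    5 Hz transition), bandpass 70–200 Hz, standardize.
    """
    wave, audio_rate = _waveform_and_rate(stimulus, rate)
    x = resample_antialias(wave, audio_rate, target_rate)
    x = highgamma_bandpass(x, target_rate)
    values, degenerate = standardize(x)
    return Predictor(values, target_rate, "carrier", source_label, degenerate)


def auditory_spectrogram(
    stimulus,
    rate: float | None = None,
    n_bins: int = 128,
    fmin: float = 180.0,
    bins_per_octave: int = 24,
    frame_rate: float = 1000.0,
    q10db: float = 3.0,
) -> AuditorySpectrogram:
    """Simplified auditory-periphery spectrogram.

    A bank of ``n_bins`` overlapping bandpass filters with Q10dB ≈ ``q10db``,
    spaced ``bins_per_octave`` per octave from ``fmin`` (128 bins at 24/octave
    span 5.3 octaves).  Per band: order-4 Butterworth bandpass (zero-phase),
    half-wave rectification, lowpass smoothing, and decimation to
    ``frame_rate`` — millisecond time resolution.  The hair-cell nonlinearity
    and lateral-inhibition stages of full peripheral models are deliberately
    omitted; what matters downstream is the F0-rate modulation of each band's
    envelope, which this simplified bank preserves.
    """
    wave, audio_rate = _waveform_and_rate(stimulus, rate)
    cfs = fmin * 2.0 ** (np.arange(n_bins) / bins_per_octave)
    # for a 4-pole Butterworth bandpass, the -10 dB bandwidth is 3^(1/4) ≈ 1.732
    # times the half-power bandwidth, so Q10dB = 3 maps to Q3dB ≈ 5.196
    q3db = q10db * 3.0 ** 0.25
    top_edge = cfs[-1] * (1.0 + 0.5 / q3db)
    if top_edge >= audio_rate / 2.0:
        raise ValueError(
            f"filterbank top edge {top_edge:.0f} Hz reaches Nyquist "
            f"({audio_rate / 2.0:.0f} Hz)"
        )
    if frame_rate < 1000.0:
        warnings.warn("frame_rate below 1 kHz loses millisecond resolution", stacklevel=2)
    decim = audio_rate / frame_rate
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError("audio rate must be an integer multiple of frame_rate")
    decim = int(round(decim))
    sos_lp = signal.butter(4, 0.4 * frame_rate, btype="low", fs=audio_rate, output="sos")
    envelopes = np.empty((n_bins, int(np.ceil(wave.size / decim))))
    for i, cf in enumerate(cfs):
        bw = cf / q3db
        sos = signal.butter(
            2, [cf - bw / 2.0, cf + bw / 2.0], btype="band", fs=audio_rate, output="sos"
        )
        band = signal.sosfiltfilt(sos, wave)
        env = signal.sosfiltfilt(sos_lp, np.maximum(band, 0.0))
        envelopes[i] = np.maximum(env[::decim], 0.0)
    return AuditorySpectrogram(cfs, envelopes, frame_rate)


def envelope_modulations_predictor(
    stimulus,
    rate: float | None = None,
    band_lo: float = 300.0,
    band_hi: float = 4000.0,
    target_rate: float = DEFAULT_RESPONSE_RATE,
    frame_rate: float = 1000.0,
    n_bins: int = 128,
    fmin: float = 180.0,
    source_label: str = "",
) -> Predictor:
    """Envelope modulations predictor.

    Auditory-spectrogram bands with center frequencies in
    [``band_lo``, ``band_hi``] are each bandpassed to 70–200 Hz (at the
    spectrogram frame rate), averaged across bands, resampled to
    ``target_rate``, and standardized.
    """
    spec = auditory_spectrogram(
        stimulus, rate=rate, n_bins=n_bins, fmin=fmin, frame_rate=frame_rate
    )
    sel = (spec.bins_hz >= band_lo) & (spec.bins_hz <= band_hi)
    if not sel.any():
        raise ValueError(
            f"no spectrogram bins fall in [{band_lo}, {band_hi}] Hz"
        )
    modulated = highgamma_bandpass(spec.envelopes[sel], spec.frame_rate, axis=-1)
    avg = modulated.mean(axis=0)
    x = resample_antialias(avg, spec.frame_rate, target_rate)
    values, degenerate = standardize(x)
    return Predictor(values, target_rate, "envelope_modulations", source_label, degenerate)


def concatenate_predictors(predictors: list[Predictor]) -> Predictor:
    """End-to-end concatenation of per-trial standardized predictors.

    Standardization happens per trial *before* concatenation; block boundaries
    are recorded in ``block_lengths`` (order-preserving).
    """
    if not predictors:
        raise ValueError("nothing to concatenate")
    first = predictors[0]
    for p in predictors[1:]:
        if p.rate != first.rate or p.kind != first.kind:
            raise ValueError("concatenation requires equal rates and kinds")
    values = np.concatenate([p.values for p in predictors])
    blocks = tuple(n for p in predictors for n in p.block_lengths)
    label = "+".join(p.source_label for p in predictors if p.source_label)
    return Predictor(
        values,
        first.rate,
        first.kind,
        label,
        degenerate=all(p.degenerate for p in predictors),
        block_lengths=blocks,
    )


def estimate_f0(
    stimulus,
    rate: float | None = None,
    fmin: float = 60.0,
    fmax: float = 300.0,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.5,
) -> F0Summary:
    """Time-averaged F0 by frame-wise normalized autocorrelation.

    25 ms frames with 10 ms hop; the candidate lag range covers
    [1/fmax, 1/fmin].  Frames whose best normalized autocorrelation peak falls
    below ``voicing_threshold`` are unvoiced.  To avoid octave errors the
    shortest lag within 5% of the frame's best peak is taken.  Returns the
    mean and sd of F0 over voiced frames plus the voiced fraction; with no
    voiced frame the mean is NaN and ``voiced_fraction`` is 0.
    """
    wave, audio_rate = _waveform_and_rate(stimulus, rate)
    n_frame = int(round(frame_s * audio_rate))
    hop = int(round(hop_s * audio_rate))
    lag_min = max(2, int(np.floor(audio_rate / fmax)))
    lag_max = int(np.ceil(audio_rate / fmin))
    if lag_max >= n_frame:
        raise ValueError("frame too short for the requested fmin")
    starts = np.arange(0, wave.size - n_frame + 1, hop)
    if starts.size == 0:
        return F0Summary(float("nan"), float("nan"), 0.0)
    frames = np.stack([wave[s : s + n_frame] for s in starts])
    frames = frames - frames.mean(axis=1, keepdims=True)
    # cross-correlation between the frame and its lagged copy, normalized by
    # the energies of the two overlapping windows (true correlation in [-1, 1])
    nfft = int(2 ** np.ceil(np.log2(2 * n_frame)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    raw = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : lag_max + 1]
    sq = frames**2
    csum = np.concatenate(
        [np.zeros((frames.shape[0], 1)), np.cumsum(sq, axis=1)], axis=1
    )
    total = csum[:, -1:]
    lags = np.arange(lag_min, lag_max + 1)
    # energy of x[0:n-k] and x[k:n] for each lag k
    e1 = csum[:, n_frame - lags] - csum[:, 0:1]
    e2 = total - csum[:, lags]
    denom = np.sqrt(np.maximum(e1 * e2, 1e-300))
    corr = raw[:, lag_min : lag_max + 1] / denom
    best = corr.max(axis=1)
    voiced = best >= voicing_threshold
    if not voiced.any():
        return F0Summary(float("nan"), float("nan"), 0.0)
    f0s = []
    for i in np.flatnonzero(voiced):
        row = corr[i]
        # shortest lag within 5% of the best peak guards against octave errors
        k = int(np.argmax(row >= best[i] * 0.95))
        lag = float(lags[k])
        if 0 < k < row.size - 1:  # parabolic refinement
            a, b, c = row[k - 1], row[k], row[k + 1]
            denom2 = a - 2 * b + c
            if abs(denom2) > 1e-12:
                lag += 0.5 * (a - c) / denom2
        f0s.append(audio_rate / lag)
    f0s = np.asarray(f0s)
    return F0Summary(
        float(f0s.mean()), float(f0s.std()), float(voiced.mean())
    )
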