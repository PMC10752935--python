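"""Circular-shift null models and noise-floor subtraction.

Rotating a predictor in time preserves its marginal distribution and
autocorrelation (up to rotation) while destroying its alignment with the
response, so kernels refitted to shifted predictors estimate the analysis
noise floor: the response the estimator attributes to the predictor's typical
temporal structure rather than to time-locking.  Three shifted copies at 1/4,
2/4 and 3/4 of the total duration are refitted with the identical estimator
configuration, their amplitude envelopes averaged, and the average subtracted
from the true kernel amplitude before peak analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .predictors import Predictor
from .synth import SourceRecording
from .trf import LagBasis, TRFFit, boost_trf, trf_amplitude

SHIFT_FRACTIONS = (0.25, 0.5, 0.75)

__all__ = [
    "NullEnsemble",
    "SHIFT_FRACTIONS",
    "circular_shift",
    "build_null_ensemble",
    "subtract_noise_floor",
]


@dataclass
class NullEnsemble:
    shifted_fits: list[TRFFit]
    average_amplitude: np.ndarray        # (V, P, L)
    shift_fractions: tuple[float, ...] = SHIFT_FRACTIONS

    def __post_init__(self) -> None:
        if len(self.shifted_fits) != len(self.shift_fractions):
            raise ValueError("one fit per shift fraction required")


def circular_shift(predictor: Predictor, fraction: float) -> Predictor:
    """Rotate the series by round(fraction * length) samples with wrap-around."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    shift = int(round(fraction * predictor.n_samples))
    return Predictor(
        np.roll(predictor.values, shift),
        predictor.rate,
        predictor.kind,
        predictor.source_label,
        predictor.degenerate,
        predictor.block_lengths,
    )


def build_null_ensemble(
    predictors: list[Predictor],
    response: SourceRecording,
    basis: LagBasis,
    **trf_config,
) -> NullEnsemble:
    """Refit TRFs with all predictors coherently rotated by 1/4, 2/4, 3/4.

    All predictors within one null member shift by the same fraction, keeping
    their cross-predictor correlation structure intact.  The estimator
    configuration is identical to the true fit's.
    """
    fits = []
    for frac in SHIFT_FRACTIONS:
        shifted = [circular_shift(p, frac) for p in predictors]
        fits.append(boost_trf(shifted, response, basis, **trf_config))
    average = np.mean([trf_amplitude(f) for f in fits], axis=0)
    return NullEnsemble(fits, average)


def subtract_noise_floor(true_fit: TRFFit, null: NullEnsemble) -> np.ndarray:
    """Noise-floor-corrected amplitude: |h(τ)| minus the null average; may be negative."""
    corrected = trf_amplitude(true_fit) - null.average_amplitude
    if corrected.shape != null.average_amplitude.shape:
        raise ValueError("fit and null ensemble shapes differ")
    return corrected
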