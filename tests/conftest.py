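import numpy as np
import pytest

from hgtrf.predictors import Predictor, highgamma_bandpass, standardize
from hgtrf.trf import build_basis


@pytest.fixture(scope="session")
def basis():
    """Default lag basis: -40..210 ms at 500 Hz, 4 ms Hamming windows."""
    return build_basis()


@pytest.fixture(scope="session")
def band_predictor():
    """Factory for unit-sd 70-200 Hz band-limited noise predictors."""

    def make(seed: int, n: int = 6000, rate: float = 500.0, label: str = "") -> Predictor:
        z = np.random.default_rng(seed).normal(size=n)
        v, _ = standardize(highgamma_bandpass(z, rate))
        return Predictor(v, rate, "carrier", label or f"bp{seed}")

    return make
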