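import numpy as np
import pytest

from foulcast.cos2d import SpectraSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_series(rng):
    """Small random spectra series on uniform times (8 wavenumbers × 12 t)."""
    return SpectraSeries(
        wavenumbers=np.linspace(800.0, 1800.0, 8),
        times=np.arange(12.0),
        absorbance=rng.normal(size=(8, 12)),
    )


def sinusoid_series(phases, m=48):
    """Bands sin(ωt − φ) sampled over one full period (zero-mean by design)."""
    t = np.arange(m, dtype=float)
    omega = 2.0 * np.pi / m
    rows = [np.sin(omega * t - phi) for phi in phases]
    nu = 1000.0 + 100.0 * np.arange(len(phases))
    return SpectraSeries(wavenumbers=nu, times=t, absorbance=np.vstack(rows))
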