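import numpy as np
import pandas as pd
import pytest

from specfresh.spectra_io import SpectralCube, SpectrumSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_set(rng):
    """A 6-sample, 20-band SpectrumSet with labels and indicators."""
    wl = np.linspace(400, 1000, 20)
    values = 0.5 + 0.1 * rng.random((6, 20))
    labels = np.array(
        ["Fresh", "Fresh", "SubFresh", "PreSpoiled", "Spoiled", "Spoiled"], dtype=object
    )
    indicators = pd.DataFrame(
        {
            "tvbn": [6.0, 7.0, 18.0, 20.0, 40.0, 55.0],
            "tac": [4.4, 4.5, 5.0, 5.5, 6.3, 6.5],
            "mpn": [4.4, 4.5, 4.9, 5.5, 6.8, 7.1],
        }
    )
    return SpectrumSet(values=values, wavelengths=wl, labels=labels, indicators=indicators)


@pytest.fixture
def tiny_cube():
    """4x4x3 cube with known dark/white frames."""
    rows, cols, bands = 4, 4, 3
    data = np.arange(rows * cols * bands, dtype=float).reshape(rows, cols, bands) + 10
    dark = np.zeros(bands)
    white = np.full(bands, 100.0)
    return SpectralCube(data=data, dark=dark, white=white, wavelengths=np.array([400.0, 500.0, 600.0]))
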