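import numpy as np
import pytest

from csppnet.spectra_io import Peak, Spectrum
from csppnet.synthetic import SimConfig, simulate_metabolome


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated metabolome (10 scaffolds) shared across tests."""
    return simulate_metabolome(SimConfig(seed=7, n_scaffolds=10))


@pytest.fixture(scope="session")
def fixture_sim():
    """The canonical full-size fixture (50 scaffolds, 8-code grammar)."""
    from csppnet.synthetic import fixture_config

    return simulate_metabolome(fixture_config())


def make_spectrum(peaks, spectrum_id="s", precursor_mz=300.0, rt=10.0, polarity="neg",
                  instrument="FT", ms_level=2):
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz,
        rt=rt,
        polarity=polarity,
        instrument=instrument,
        ms_level=ms_level,
        peaks=[Peak(float(m), float(i)) for m, i in peaks],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
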