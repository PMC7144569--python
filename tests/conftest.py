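import numpy as np
import pytest

from serumaf.library import get_components
from serumaf.lineshape import gmg_value, solve_band
from serumaf.simulate import GRID
from serumaf.spectra import Spectrum


@pytest.fixture(scope="session")
def library_366():
    return get_components(366, "control")


@pytest.fixture(scope="session")
def library_310():
    return get_components(310, "control")


def build_spectrum(components, amplitudes, excitation=366, sample_id="synthetic",
                   group="other", noise_sd=0.0, rng=None):
    """Construct a spectrum as an exact sum of library component bands.

    ``noise_sd`` is expressed in a.u. on the peak-normalized scale
    (i.e. relative to a spectrum maximum of 100), matching the
    convention used for measured spectra.
    """
    curve = np.zeros_like(GRID)
    for comp, amp in zip(components, amplitudes):
        band = solve_band(comp.shape, amp)
        v = gmg_value(band, GRID)
        curve += -v if comp.role == "negative" and amp > 0 else v
    if noise_sd > 0:
        sd = noise_sd * float(np.max(curve)) / 100.0
        curve = curve + (rng or np.random.default_rng(0)).normal(0, sd, GRID.size)
    return Spectrum(GRID.copy(), curve, excitation, sample_id, group)
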