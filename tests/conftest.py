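import numpy as np
import pytest

from phenoscreen.synthetic_data import (
    CTRL_BOUTS, BoutParams, OKRSimParams, ScreenSpec, StackSpec,
    simulate_bout_track, simulate_nystagmogram, simulate_screen,
    simulate_synapse_stack,
)


@pytest.fixture(scope="session")
def ctrl_track_1h():
    """One hour of control swimming in constant light, open arena
    (negligible wall contact) for unbiased parameter recovery."""
    return simulate_bout_track(CTRL_BOUTS, [(3600.0, "light")], 25.0,
                               seed=101, well_radius_mm=100.0)


@pytest.fixture(scope="session")
def recovery_track_1h():
    """Track with a long planted inter-movement interval (8 s) to probe
    IMI recovery."""
    params = BoutParams(imi_mean=8.0)
    return simulate_bout_track(params, [(3600.0, "light")], 25.0,
                               seed=102, well_radius_mm=100.0)


@pytest.fixture(scope="session")
def default_nystagmogram():
    return simulate_nystagmogram(OKRSimParams(gain=0.8), seed=103)


@pytest.fixture(scope="session")
def default_screen():
    return simulate_screen(ScreenSpec(), seed=104)


@pytest.fixture(scope="session")
def noiseless_stack():
    """2 cells x 5 inside puncta, no outside puncta, no noise."""
    return simulate_synapse_stack(StackSpec(), seed=105)


@pytest.fixture(scope="session")
def snr5_stack():
    """20 cells x 10 inside puncta at snr 5."""
    spec = StackSpec(shape=(48, 256, 256), n_cells=20,
                     puncta_inside_per_cell=10, snr=5.0)
    return simulate_synapse_stack(spec, seed=106)
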