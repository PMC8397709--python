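import numpy as np
import pytest

import isletwave as iw


@pytest.fixture(scope="session")
def geometry():
    """A mid-sized islet: 24 cells in a 60 um radius, 12 um spacing."""
    return iw.make_islet_geometry(24, islet_radius=60.0, min_spacing=12.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_wave(geometry):
    """Noiseless full-wave capture at 50 um/s with its ground truth."""
    params = iw.SimulationParams(level=3, wave_velocity=50.0, noise_sd=0.0, seed=11)
    return iw.simulate_recording(geometry, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
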