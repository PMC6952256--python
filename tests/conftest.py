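import numpy as np
import pytest

from endodefog import generate_scene, simulate_foggy_frame


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def vessel_scene():
    """Clean endoscopy-like frame with its heavy-plume transmission field."""
    clean, transmission = generate_scene(96, 72, seed=11)
    return clean, transmission


@pytest.fixture(scope="session")
def heavy_fixture():
    """Full heavy-smoke fixture dict (clean/transmission/veil/hazy)."""
    return simulate_foggy_frame(240, 160, preset="heavy", seed=5)


@pytest.fixture(scope="session")
def thin_fixture():
    return simulate_foggy_frame(240, 160, preset="thin", seed=5)


def random_frame(rng, height=24, width=32):
    return rng.uniform(0.0, 1.0, size=(height, width, 3))
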