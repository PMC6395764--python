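import numpy as np
import pytest

from erquant import AnalysisConfig
from erquant.synth import generate_network_scene, generate_straight_tubule


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig(fwhm_min_px=5.0, fwhm_max_px=12.0)


@pytest.fixture(scope="session")
def scene():
    """A mid-density tubule-only scene with light noise."""
    return generate_network_scene(n_polygons=30, cisterna_fraction=0.0,
                                  noise_sd=0.0083, seed=3)


@pytest.fixture(scope="session")
def scene_with_cisternae():
    return generate_network_scene(n_polygons=25, cisterna_fraction=0.2,
                                  noise_sd=0.01, seed=11)


@pytest.fixture(scope="session")
def straight_tube():
    """One isolated 40 nm-radius horizontal tubule, noise-free."""
    return generate_straight_tubule(radius_nm=40.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
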