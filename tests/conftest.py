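import numpy as np
import pytest

from rppaquant import NoiseSpec, make_dilution_layout, render_array
from rppaquant.experiments import DEFAULT_PARAMS


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def small_layout():
    """Three standard 15-spot series plus a bright control series."""
    return make_dilution_layout(["s0", "s1", "s2", "pos"])


@pytest.fixture(scope="session")
def small_conc():
    return {"s0": 0.8, "s1": 0.4, "s2": 0.2, "pos": 8.0}


@pytest.fixture(scope="session")
def rendered(small_layout, small_conc, params):
    """One default-noise rendered array with its ground truth."""
    image, truth = render_array(small_layout, params, small_conc,
                                NoiseSpec(), seed=42)
    return image, truth


@pytest.fixture(scope="session")
def rendered_clean(small_layout, small_conc, params):
    """A noise-free, flat-background rendering (exact-arithmetic checks)."""
    noise = NoiseSpec(multiplicative_cv=0.0, read_noise_sd=0.0,
                      background_level=100.0, background_gradient=0.0,
                      spot_jitter_sd=0.0)
    image, truth = render_array(small_layout, params, small_conc,
                                noise, seed=7)
    return image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
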