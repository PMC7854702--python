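import logging

import numpy as np
import pytest

from phytosaxs import bead_models as bm
from phytosaxs import saxs_core as sc

logging.getLogger("phytosaxs").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere_model():
    """Dense uniform sphere fill, R = 30 A (Rg oracle sqrt(3/5)*30)."""
    return bm.generate_shape("sphere", {"radius": 30.0}, 4000, seed=101)


@pytest.fixture(scope="session")
def gaussian_profile():
    """Profile generated exactly from the Guinier law, I0=50, Rg=50 A."""
    s = np.linspace(1e-3, 0.01, 60)
    intensity = 50.0 * np.exp(-(4.0 * np.pi ** 2 / 3.0) * 50.0 ** 2 * s ** 2)
    return sc.ScatteringProfile(s=s, intensity=intensity, sigma=np.ones_like(s))
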