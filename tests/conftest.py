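import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mitodyn.netsim import FiberGeometry, RenderOptics, simulate_experiment


@pytest.fixture(scope="session")
def small_geometry() -> FiberGeometry:
    return FiberGeometry(n_long=24, n_trans=8)


@pytest.fixture(scope="session")
def noise_free_optics() -> RenderOptics:
    return RenderOptics(photon_scale=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def sharp_optics() -> RenderOptics:
    """No blur and no noise: images are exact paintings."""
    return RenderOptics(blur_sigma_um=0.0, photon_scale=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def control_series():
    """One default-geometry control fiber, rendered with default optics."""
    return simulate_experiment("control", seed=12345)


@pytest.fixture(scope="session")
def control_series_small(small_geometry):
    return simulate_experiment("control", small_geometry, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
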