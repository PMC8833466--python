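import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import pancdwi as p


@pytest.fixture(scope="session")
def small_rfov():
    """Reduced-FOV geometry on a small grid (fast rasterization)."""
    return p.RFOV.scaled((48, 48, 8))


@pytest.fixture(scope="session")
def small_ffov():
    return p.FFOV.scaled((48, 48, 8))


@pytest.fixture(scope="session")
def noiseless_phantom(small_rfov):
    return p.make_phantom(small_rfov, lesion_diameter_mm=14.0)


@pytest.fixture(scope="session")
def noiseless_stack(noiseless_phantom):
    return p.simulate_dwi(noiseless_phantom, p.RFOV_PROTOCOL_600, noise_sigma=0.0, seed=0)
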