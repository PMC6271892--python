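import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import micellometry as m

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sphere_model():
    """Uniform bead sphere R = 20 Å, enough beads for ~1% Monte-Carlo error."""
    model, truth = m.make_ellipsoid(20.0, 20.0, 20.0, 20000, seed=101)
    return model, truth


@pytest.fixture(scope="session")
def prolate_model():
    """Uniform prolate with the micelle-like 75 × 42 × 42 Å envelope."""
    model, truth = m.make_ellipsoid(37.5, 21.0, 21.0, 20000, seed=102)
    return model, truth


@pytest.fixture(scope="session")
def small_prolate():
    """Cheap prolate for tests that only need a valid bead model."""
    return m.make_ellipsoid(30.0, 15.0, 15.0, 800, seed=103)


@pytest.fixture()
def q_grid():
    return np.linspace(0.02, 0.6, 60)
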