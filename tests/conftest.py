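import numpy as np
import pytest

from sonoservo import PhantomConfig, canonical_probe_pose, generate_geometry


@pytest.fixture(scope="session")
def config():
    """Default clinical-scale phantom configuration."""
    return PhantomConfig()

@pytest.fixture(scope="session")
def geometry(config):
    return generate_geometry(config)


@pytest.fixture(scope="session")
def centered_pose(config):
    """Probe directly over the vessel a little inside its entry point."""
    return canonical_probe_pose(config, u_mm=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240725)
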