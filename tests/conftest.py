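import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_connectome():
    """A connected 20-region modular connectome shared across tests."""
    from eigenmarkers import generate_connectome

    return generate_connectome(n_regions=20, n_modules=3, seed=7)


@pytest.fixture(scope="session")
def small_basis(small_connectome):
    from eigenmarkers import connectome_basis

    return connectome_basis(small_connectome)
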