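import numpy as np
import pytest

from kidneymorph import generate_template_shape, vertex_geometry


@pytest.fixture(scope="session")
def small_template():
    """~300-vertex bean template shared across tests."""
    return generate_template_shape(300, bend=0.4, seed=0)


@pytest.fixture(scope="session")
def small_geometry(small_template):
    return vertex_geometry(small_template)


@pytest.fixture(scope="session")
def tiny_template():
    """~130-vertex template for brute-force comparisons."""
    return generate_template_shape(130, bend=0.4, seed=0)


@pytest.fixture(scope="session")
def tiny_geometry(tiny_template):
    return vertex_geometry(tiny_template)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
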