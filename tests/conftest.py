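import numpy as np
import pytest

import tjbarrier as tj


@pytest.fixture(scope="session")
def fig_network():
    """The small illustrative lattice: three strands, three compartments wide."""
    return tj.build_network(tj.GeometryParams(n_strand=3, width_compartments=3))


@pytest.fixture(scope="session")
def default_network():
    """Full-size default lattice (4 strands, 50 compartments wide)."""
    return tj.build_network(tj.GeometryParams())


@pytest.fixture(scope="session")
def small_network():
    """Small lattice for fast stochastic tests."""
    return tj.build_network(tj.GeometryParams(n_strand=3, width_compartments=10))


@pytest.fixture(scope="session")
def presets():
    return tj.load_presets()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
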