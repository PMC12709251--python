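import numpy as np
import pytest

from memstress import ElasticConstants, InterfaceGeometry, sample_profile


@pytest.fixture
def default_geom():
    """Standard geometry: lme = 5 nm, epsilon = 5/6 nm."""
    return InterfaceGeometry.default()


@pytest.fixture
def full_params():
    """A parameter set with every component active."""
    return ElasticConstants(k=20.0, kG0=-14.0, m=0.1, gamma=0.005)


@pytest.fixture
def symmetric_params():
    """Tensionless symmetric membrane (kG0/k = -0.7)."""
    return ElasticConstants(k=20.0, kG0=-14.0, m=0.0, gamma=0.0)


@pytest.fixture
def wide_profile(full_params, default_geom):
    """A profile wide and dense enough for accurate Simpson moments."""
    lme = default_geom.lme
    return sample_profile(full_params, default_geom, -4 * lme, 4 * lme, 2001)


@pytest.fixture
def ugrid():
    return np.linspace(-8.0, 8.0, 641)
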