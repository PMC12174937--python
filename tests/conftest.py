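import numpy as np
import pytest

from hexsca import DensityField, GridSpec, ParamField


@pytest.fixture
def grid5():
    return GridSpec(5, 5)


@pytest.fixture
def grid8():
    return GridSpec(8, 8)


@pytest.fixture
def base_params():
    """Base simulation-study parameter settings."""
    return ParamField(gamma1=0.8, gamma2=0.8, phi=1 / 3, rho=1 / 3)


@pytest.fixture
def single_cell_field():
    """A 4x4 field with one affected cell of full density at (1, 1)."""
    v = np.zeros((4, 4))
    v[1, 1] = 1.0
    return DensityField(v)


def random_field(rng, m, n, p_affected=0.3):
    """A random density field with roughly p_affected occupied cells."""
    v = rng.uniform(0.05, 1.0, size=(m, n))
    v[rng.random((m, n)) > p_affected] = 0.0
    return DensityField(v)
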