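import numpy as np
import pytest

from vasotherm.core import (
    DEFAULT_TUMOR_BOX,
    Quantity,
    ScalarField,
    TissueProperties,
    make_grid,
    region_mask,
)
from vasotherm.vasculature import assign_flows, build_network


@pytest.fixture(scope="session")
def grid():
    """The canonical 82 x 80 x 80 mm control volume at 2 mm spacing."""
    return make_grid((82, 80, 80), 2)


@pytest.fixture(scope="session")
def props():
    return TissueProperties()


@pytest.fixture(scope="session")
def network(grid):
    """Canonical network, gamma = 0.7, flows for w_b = 0.5 kg m^-3 s^-1."""
    return assign_flows(build_network(grid, gamma=0.7), 0.5)


@pytest.fixture(scope="session")
def tumor_mask(grid):
    return region_mask(grid, DEFAULT_TUMOR_BOX)


@pytest.fixture()
def uniform_tumor_power(grid, tumor_mask):
    q = np.zeros(grid.shape)
    q[tumor_mask] = 1e5
    return ScalarField(grid, q, Quantity.power_Wm3)


def small_grid(n=9, spacing=2.0):
    ext = (spacing * (n - 1),) * 3
    return make_grid(ext, spacing)


@pytest.fixture()
def grid9():
    return small_grid(9)
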