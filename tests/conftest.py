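import numpy as np
import pytest

from rhombosim.geometry import DimensionTable, Geometry, fit_dimension_curves


@pytest.fixture(scope="session")
def table():
    return DimensionTable.default()


@pytest.fixture(scope="session")
def curves(table):
    return fit_dimension_curves(table)


@pytest.fixture(scope="session")
def geometry():
    return Geometry.default("rapid")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
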