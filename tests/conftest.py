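import numpy as np
import pytest

from bhkit.physics import PHANTOM_MEDIUM, load_pressure_table, pressure_measurements


@pytest.fixture(scope="session")
def medium():
    return PHANTOM_MEDIUM


@pytest.fixture(scope="session")
def pressure_table():
    return load_pressure_table()


@pytest.fixture(scope="session")
def measurements():
    return pressure_measurements()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
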