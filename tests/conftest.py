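import numpy as np
import pytest

from hyperscan.coilfield import DriverElectronics, build_matrix_coil
from hyperscan.synthscenario import RemnantFieldModel, two_person_setup


@pytest.fixture(scope="session")
def coil_array():
    return build_matrix_coil()


@pytest.fixture(scope="session")
def electronics():
    return DriverElectronics()


@pytest.fixture(scope="session")
def touch_setup():
    """Two full 16-sensor helmets at the touch-task separation."""
    return two_person_setup(0.65)


@pytest.fixture(scope="session")
def small_setup():
    """Two reduced helmets (6 sensors, 4 nulling) for fast controller tests."""
    return two_person_setup(0.65, n_sensors=6, n_nulling=4)


@pytest.fixture()
def static_remnant():
    """Default remnant field with the slow drift switched off."""
    rem = RemnantFieldModel.msr_default(seed=11)
    rem.drift_magnitude = 0.0
    return rem


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
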