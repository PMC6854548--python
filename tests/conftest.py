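import numpy as np
import pytest

from oscbeam import SensorArray, SphericalHeadModel, build_sensor_array


@pytest.fixture(scope="session")
def head():
    return SphericalHeadModel(center=np.zeros(3), radius=0.09)


@pytest.fixture(scope="session")
def sensors64():
    return build_sensor_array(64, helmet_radius=0.12, coverage_angle=120,
                              seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_channel_sensors():
    return SensorArray(channel_ids=["MAG001"],
                       positions=np.array([[0.0, 0.0, 0.12]]),
                       orientations=np.array([[0.0, 0.0, 1.0]]))
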