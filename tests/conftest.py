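import numpy as np
import pytest

from vesselquant import InstanceRecord, PixelCalibration, make_scenario


@pytest.fixture(scope="session")
def calib():
    return PixelCalibration()  # 0.137 µm/px


def make_instance(id, x, y, area, area_px=0):
    """Shorthand for building instance records in geometric tests."""
    return InstanceRecord(
        id=id, centroid_x_um=x, centroid_y_um=y, area_um2=area, area_px=area_px
    )


@pytest.fixture(scope="session")
def clean_scenario():
    return make_scenario("clean", seed=11)


@pytest.fixture(scope="session")
def speck_scenario():
    return make_scenario("speck-noise", seed=12)


@pytest.fixture(scope="session")
def dropout_scenario():
    return make_scenario("dropout", seed=13)


@pytest.fixture(scope="session")
def fragment_scenario():
    return make_scenario("fragmented-large", seed=14)


@pytest.fixture(scope="session")
def low_prevalence_scenario():
    return make_scenario("low-prevalence", seed=15)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
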