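import numpy as np
import pytest

from fhposture import (
    SimulationConfig,
    bundled_table_path,
    fit_channel_calibration,
    load_calibration_table,
)

# transcription of the bundled voltage/angle table, used as the independent
# reference in calibration tests
TABLE_DEGREES = [-60, -50, -40, -30, -20, -10, 0, 10, 20, 30, 40, 50, 60]
TABLE_FLEX = [1065, 1117, 1187, 1273, 1345, 1443, 1500, 1655, 1720, 1811, 1903, 1998, 2112]
TABLE_X = [917, 996, 1119, 1213, 1316, 1453, 1590, 1740, 1841, 1966, 2098, 2196, 2290]
TABLE_Y = [943, 998, 1113, 1216, 1312, 1461, 1622, 1768, 1911, 2034, 2141, 2261, 2320]
TABLE_Z = [950, 996, 1113, 1204, 1335, 1486, 1634, 1778, 1883, 1995, 2137, 2257, 2324]


@pytest.fixture(scope="session")
def table():
    return load_calibration_table(bundled_table_path())


@pytest.fixture(scope="session")
def flex_cal(table):
    return fit_channel_calibration(table, "flex")


@pytest.fixture(scope="session")
def x_cal(table):
    return fit_channel_calibration(table, "x")


@pytest.fixture
def sim_config():
    def make(seed=0, noise_mv=2.0, rate=100.0, **kw):
        return SimulationConfig(seed=seed, noise_mv=noise_mv, rate=rate, **kw)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
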