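import numpy as np
import pytest

from gazecond.geometry import ViewingGeometry
from gazecond.scenarios import end_to_end_recovery

SCENARIO_SEED = 1


@pytest.fixture(scope="session")
def geometry():
    return ViewingGeometry(10.0, (64, 64))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def null_report():
    return end_to_end_recovery("null", SCENARIO_SEED)


@pytest.fixture(scope="session")
def linear_report():
    return end_to_end_recovery("linear", SCENARIO_SEED)


@pytest.fixture(scope="session")
def central_bias_report():
    return end_to_end_recovery("central_bias", SCENARIO_SEED)


@pytest.fixture(scope="session")
def interest_report():
    return end_to_end_recovery("interest", SCENARIO_SEED)


@pytest.fixture(scope="session")
def rank_report():
    return end_to_end_recovery("rank", SCENARIO_SEED)


@pytest.fixture(scope="session")
def duration_report():
    return end_to_end_recovery("duration", SCENARIO_SEED)
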