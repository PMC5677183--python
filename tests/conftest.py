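import numpy as np
import pytest

from edaflow.acquisition import SensorConfig
from edaflow.synthetic import (CohortConfig, EffectModel, ProtocolConfig,
                               make_schedule)


@pytest.fixture
def sensor():
    return SensorConfig()


@pytest.fixture
def protocol():
    return ProtocolConfig()


@pytest.fixture
def effect():
    return EffectModel()


@pytest.fixture
def schedule(protocol):
    sched, bounds = make_schedule(protocol, seed=7)
    return sched


@pytest.fixture
def schedule_with_bounds(protocol):
    return make_schedule(protocol, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
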