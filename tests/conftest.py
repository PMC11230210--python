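import numpy as np
import pytest

import strideadapt as sa


@pytest.fixture(scope="session")
def protocol():
    return sa.Protocol()


@pytest.fixture(scope="session")
def schedule(protocol):
    sched, _ = sa.build_protocol(protocol)
    return sched


@pytest.fixture(scope="session")
def truth_spec():
    return sa.default_truth()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def step_schedule():
    """Short schedule: 5 zero strides then a sustained unit input."""
    return np.r_[np.zeros(5), np.ones(25)]
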