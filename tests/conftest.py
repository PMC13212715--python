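import numpy as np
import pytest

from steadytorque.signal_processing import TimeSeriesChannel
from steadytorque.synthetic_data import SimConfig

FS = 2000.0

NOISE_FREE = dict(
    torque_noise_cv=0.0,
    baseline_noise_sd=0.0,
    emg_noise_cv=0.0,
    emg_baseline_noise=0.0,
    fascicle_noise_sd=0.0,
    baseline_offset=0.0,
)


def make_channel(values, fs=FS, name="sig", t0=0.0, units=""):
    return TimeSeriesChannel(name=name, sampling_rate=fs, values=np.asarray(values, float), t0=t0, units=units)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_exp1():
    return SimConfig(experiment=1, seed=11, **NOISE_FREE)


@pytest.fixture
def noise_free_exp2():
    return SimConfig(experiment=2, seed=11, **NOISE_FREE)
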