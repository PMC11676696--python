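import numpy as np
import pytest

from tricadence import (
    ImuRecording,
    SyntheticSessionSpec,
    simulate_discipline,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(n=1000, sample_rate_hz=100.0, seed=0, **channels):
    """A small valid recording with optional channel overrides."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sample_rate_hz
    data = {c: rng.normal(0, 0.05, n) for c in
            ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")}
    data.update({k: np.asarray(v, dtype=float) for k, v in channels.items()})
    return ImuRecording(t=t, sample_rate_hz=sample_rate_hz, **data)


@pytest.fixture
def small_recording():
    return make_recording()


@pytest.fixture
def run_session():
    """A 60 s synthetic run at 172 strides/min with exact ground truth."""
    spec = SyntheticSessionSpec("run", 60.0, 172.0, seed=7)
    return simulate_discipline(spec)
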