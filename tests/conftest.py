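import numpy as np
import pytest

import limbintent as li


@pytest.fixture(scope="session")
def library():
    return li.default_templates()


@pytest.fixture(scope="session")
def socks_trace_zero():
    """Canonical socks trace, noiseless, with ground truth."""
    return li.generate_action_trace(li.canonical_script("socks"), li.ZERO_NOISE)


@pytest.fixture(scope="session")
def socks_trace_noisy():
    """Canonical socks trace at default noise, with ground truth."""
    return li.generate_action_trace(li.canonical_script("socks"), li.NoiseSpec(seed=3))


@pytest.fixture(scope="session")
def state_dataset():
    """Small labeled state dataset for model fixtures."""
    return li.generate_state_dataset(300, seed=7)


@pytest.fixture(scope="session")
def trained_model(state_dataset):
    X = state_dataset[["var", "diff", "emax", "emin"]].to_numpy()
    y = state_dataset["state"].to_numpy()
    return li.train_state_model(X, y, sigma=0.7)


def constant_trace(n: int = 60, value: float = 10.0, rate_hz: float = 50.0) -> li.Trace:
    """A trace that never moves: every angle at `value`, every rate zero."""
    t = np.arange(n) / rate_hz
    channels = {}
    for part in li.PARTS:
        for axis in li.ANGLE_AXES:
            channels[f"{part}.{axis}"] = np.full(n, value)
        for axis in li.GYRO_AXES:
            channels[f"{part}.{axis}"] = np.zeros(n)
    return li.Trace.from_arrays(t, channels, rate_hz=rate_hz)


def ramp_trace(
    hold: int = 30,
    ramp: int = 20,
    step: float = 1.2,
    channel: str = "hand.yaw",
    rate_hz: float = 50.0,
) -> li.Trace:
    """hold -> linear ramp (per-sample step on one channel) -> hold."""
    n = hold + ramp + hold
    t = np.arange(n) / rate_hz
    values = np.concatenate([
        np.zeros(hold),
        step * np.arange(1, ramp + 1),
        np.full(hold, step * ramp),
    ])
    channels = {}
    for part in li.PARTS:
        for axis in li.ANGLE_AXES:
            name = f"{part}.{axis}"
            channels[name] = values.copy() if name == channel else np.zeros(n)
        for axis in li.GYRO_AXES:
            channels[f"{part}.{axis}"] = np.zeros(n)
    return li.Trace.from_arrays(t, channels, rate_hz=rate_hz)
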