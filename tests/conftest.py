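import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fw_trial():
    """Small two-sided forward-walking trial with default sensor noise."""
    from gaitmark.simulate import SimConfig, simulate_trial
    return simulate_trial(SimConfig(condition="FW", n_strides=12, seed=7))


@pytest.fixture(scope="session")
def bw_trial():
    """Small two-sided backward-walking trial with default sensor noise."""
    from gaitmark.simulate import SimConfig, simulate_trial
    return simulate_trial(SimConfig(condition="BW", n_strides=12, seed=7,
                                    stride_time_mean=1.48, speed=0.54))


@pytest.fixture(scope="session")
def tiny_trial():
    """Single-sided noiseless trial for IO round-trip tests."""
    from gaitmark.simulate import SimConfig, simulate_trial
    return simulate_trial(SimConfig(condition="FW", n_strides=4, seed=3,
                                    sides=("L",), noise_sd_marker=0.0,
                                    noise_sd_acc=0.0, noise_sd_gyro=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
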