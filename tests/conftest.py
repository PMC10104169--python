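import numpy as np
import pytest

from circuitsync import GroundTruth, extract_lfp, gen_coupled_lfp


@pytest.fixture(scope="session")
def coupled_rec():
    """60 s two-region session with strong theta-gamma coupling and +10 ms lag."""
    gt = GroundTruth(seed=7, pac_depth=0.9, theta_freq=8.0, gamma_freq=60.0, lag_ms=10.0)
    return gen_coupled_lfp(gt, 60.0)


@pytest.fixture(scope="session")
def coupled_lfp(coupled_rec):
    return extract_lfp(coupled_rec, notch_hz=0.0)


@pytest.fixture(scope="session")
def uncoupled_rec():
    gt = GroundTruth(seed=7, pac_depth=0.0, lag_ms=0.0)
    return gen_coupled_lfp(gt, 60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
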