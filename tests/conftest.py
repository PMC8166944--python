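import numpy as np
import pytest

from caninemsk.inverse_dynamics import newton_euler
from caninemsk.synthetic import make_synthetic_gait, make_toy_limb


@pytest.fixture(scope="session")
def toy_limb():
    return make_toy_limb()


@pytest.fixture(scope="session")
def toy_gait(toy_limb):
    """Reference synthetic walking trial on the toy limb (21 frames)."""
    pose, loads = make_synthetic_gait(toy_limb, seed=0, n_points=21)
    return pose, loads


@pytest.fixture(scope="session")
def toy_torques(toy_limb, toy_gait):
    pose, loads = toy_gait
    return newton_euler(toy_limb, pose, loads)


@pytest.fixture(scope="session")
def toy_gravity_torques(toy_limb, toy_gait):
    """Torques of the same motion without ground contact (muscle-sufficient)."""
    pose, _ = toy_gait
    return newton_euler(toy_limb, pose)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
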