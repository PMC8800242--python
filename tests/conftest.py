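import dataclasses

import numpy as np
import pytest

from elbowrom import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_config():
    """All stochastic terms off: the simulator becomes an exact linkage."""
    return SimConfig(
        pos_noise_rms=0.0,
        ori_noise_rms=0.0,
        hold_sd_deg=0.0,
        digitization_noise_mm=0.0,
        artifact_gain=0.0,
        xray_noise_sd_deg=0.0,
        seed=0,
    )


@pytest.fixture
def default_config():
    return SimConfig(seed=7)


def random_pose(rng, t=0.0):
    """Uniformly random rigid pose (helper shared across test modules)."""
    from scipy.spatial.transform import Rotation

    from elbowrom import RigidPose
    from elbowrom.rigid import rotation_quaternion

    q = rotation_quaternion(Rotation.random(rng=rng))
    return RigidPose(t=t, position=rng.uniform(-100, 100, 3), orientation=q)
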