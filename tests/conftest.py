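import numpy as np
import pytest

from ergoreba.skeleton import SkeletonFrame, SkeletonSequence
from ergoreba.synthkin import KinematicConfig, simulate_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def upright_frame():
    """Hand-built neutral standing frame: trunk vertical (+y up), subject
    facing +x, elbows flexed to 80 deg (the REBA-neutral forearm band)."""
    import math
    e = math.radians(80.0)
    pos = {
        "Head": (0.0, 0.25, 0.0),
        "Neck": (0.0, 0.0, 0.0),
        "RightShoulder": (0.0, 0.0, 0.19),
        "LeftShoulder": (0.0, 0.0, -0.19),
        "RightElbow": (0.0, -0.30, 0.19),
        "LeftElbow": (0.0, -0.30, -0.19),
        "RightWrist": (0.27 * math.sin(e), -0.30 + 0.27 * -math.cos(e), 0.19),
        "LeftWrist": (0.27 * math.sin(e), -0.30 + 0.27 * -math.cos(e), -0.19),
        "RightHip": (0.0, -0.50, 0.10),
        "LeftHip": (0.0, -0.50, -0.10),
        "RightKnee": (0.0, -0.92, 0.10),
        "LeftKnee": (0.0, -0.92, -0.10),
        "RightAnkle": (0.0, -1.34, 0.10),
        "LeftAnkle": (0.0, -1.34, -0.10),
    }
    from ergoreba.skeleton import JOINT_ORDER
    arr = np.array([pos[j.value] for j in JOINT_ORDER])
    return SkeletonFrame(arr, 0)


@pytest.fixture
def random_sequence(rng):
    """Short random-but-valid skeleton sequence (not anatomically bound)."""
    arr = rng.normal(scale=0.5, size=(25, 14, 3))
    return SkeletonSequence.from_array(arr, fps=24.0)


@pytest.fixture(scope="session")
def mixed_sequence():
    """One simulated mixed-regime sequence shared across tests."""
    return simulate_sequence(
        KinematicConfig(regime="mixed", duration=8.0, fps=30.0, seed=11))
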