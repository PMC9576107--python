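import numpy as np
import pytest

from screwaxis import (
    CylindricalJointConfig,
    ScrewAxis,
    generate_ball_swing,
    generate_cylindrical,
    generate_hinge_swing,
    twists_from_sequence,
)


@pytest.fixture(scope="session")
def cylindrical_sequence():
    """Reference ideal cylindrical joint motion (defaults: 100 Hz, one period)."""
    return generate_cylindrical(CylindricalJointConfig())


@pytest.fixture(scope="session")
def cylindrical_twists(cylindrical_sequence):
    return twists_from_sequence(cylindrical_sequence)


@pytest.fixture(scope="session")
def hinge_axis():
    return ScrewAxis(n=np.array([0.0, 0.0, 1.0]), S=np.array([0.1, 0.2, 0.0]))


@pytest.fixture(scope="session")
def hinge_sequence(hinge_axis):
    return generate_hinge_swing(hinge_axis, amplitude_deg=45.0, period_s=1.0,
                                damping_ratio=0.1, duration_s=1.0, fs=100.0)


@pytest.fixture(scope="session")
def ball_sequence():
    """Well-conditioned motion: ISAs through the origin with varying direction."""
    return generate_ball_swing(center=(0.05, -0.1, 0.02), cone_half_angle_deg=35.0,
                               amplitude_deg=50.0, duration_s=1.0, fs=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220917)


@pytest.fixture()
def make_twist_set():
    return random_twist_set


def random_twist_set(rng, n=30, scale=3.0, center=None):
    """Random well-conditioned twist set; ISAs scattered around ``center``."""
    from screwaxis import ScrewTwist, TwistSequence

    center = np.zeros(3) if center is None else np.asarray(center, float)
    twists = []
    for _ in range(n):
        w = scale * rng.normal(size=3)
        S = center + 0.05 * rng.normal(size=3)
        v0 = np.cross(S, w) + 0.02 * rng.normal(size=3)  # line through ~S plus slide
        twists.append(ScrewTwist(omega=w, v0=v0))
    return TwistSequence(twists=tuple(twists))
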