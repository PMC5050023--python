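import numpy as np
import pytest

from ktswivel.geometry import KinetochorePair


def planar_pair(theta1_deg, theta2_deg, dy=1000.0, delta1=100.0, delta2=100.0,
                pair_id=0):
    """A pair lying in the xy-plane built from signed y-swivel angles.

    Sister 0 sits at the origin, sister 1 at (0, dy, 0).  Each outer marker
    is its sister's inner marker displaced by delta along the away-from-
    sister direction rotated (counter-clockwise relative to the right-handed
    perpendicular) by its signed swivel.
    """
    t1 = np.radians(theta1_deg)
    t2 = np.radians(theta2_deg)
    inner = np.array([[0.0, 0.0, 0.0], [0.0, dy, 0.0]])
    # away directions: sister0 -> -y, sister1 -> +y
    outer = np.array([
        [delta1 * np.sin(t1), -delta1 * np.cos(t1), 0.0],
        [-delta2 * np.sin(t2), dy + delta2 * np.cos(t2), 0.0],
    ])
    return KinetochorePair(pair_id=pair_id, inner=inner, outer=outer)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
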