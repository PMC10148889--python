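import numpy as np
import pytest

from socialcircuit import ethogram as eth


@pytest.fixture
def config():
    return eth.EthogramConfig()


def make_track(mouse_id, nose_x, tail_x, fps=30.0, facing=+1,
               nose_conf=None, tail_conf=None):
    """1-D track helper: y pinned at the tube midline."""
    nose_x = np.asarray(nose_x, dtype=float)
    tail_x = np.asarray(tail_x, dtype=float)
    y = np.full_like(nose_x, 1.5)
    return eth.KeypointTrack(mouse_id, nose_x, y, tail_x, y.copy(), fps,
                             facing, nose_conf, tail_conf)


def make_bout(nose_a, tail_a, nose_b, tail_b, fps=30.0, x0=0.0, x1=30.0):
    return eth.TubeBout(make_track("A", nose_a, tail_a, fps, +1),
                        make_track("B", nose_b, tail_b, fps, -1),
                        tube_x0=x0, tube_x1=x1)


@pytest.fixture
def stationary_bout():
    n = 300
    return make_bout(np.full(n, 14.0), np.full(n, 10.0),
                     np.full(n, 16.0), np.full(n, 20.0))
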