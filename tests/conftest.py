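import numpy as np
import pytest

from axotrack import Track


def make_track(x, frame_rate=2.0, track_id=0, y=None, **kw):
    """Track from a position array sampled at a uniform frame rate."""
    x = np.asarray(x, dtype=float)
    frames = np.arange(len(x))
    return Track(track_id=track_id, frames=frames, t=frames / frame_rate,
                 x=x, y=y, **kw)


def constant_speed_track(speed, n=61, x0=100.0, frame_rate=2.0, **kw):
    """Noiseless track moving at a constant signed speed (µm/s)."""
    t = np.arange(n) / frame_rate
    return make_track(x0 + speed * t, frame_rate=frame_rate, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
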