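import numpy as np
import pytest

from clockmaze.arena import Arena, ArenaConfig, build_arena
from clockmaze.simulate import SimConfig
from clockmaze.trackio import Track, TrialRecord


@pytest.fixture(scope="session")
def arena() -> Arena:
    return build_arena(ArenaConfig())


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


def make_track(center, t=None, nose=None, tail=None, rate_hz=30.0) -> Track:
    """Build a Track from plain lists; nose/tail default to the centre offset
    by a fixed 4 cm body half-length along +x when not given."""
    center = np.asarray(center, dtype=float)
    n = len(center)
    if t is None:
        t = np.arange(n) / rate_hz
    return Track(
        t=np.asarray(t, dtype=float),
        center=center,
        nose=None if nose is None else np.asarray(nose, dtype=float),
        tail=None if tail is None else np.asarray(tail, dtype=float),
        rate_hz=rate_hz,
    )


@pytest.fixture
def straight_track():
    """Constant 10 cm/s run along +x from the origin, 30 Hz, 3 s."""
    n = 91
    t = np.arange(n) / 30.0
    x = 10.0 * t
    center = np.column_stack([x, np.zeros(n)])
    nose = center + [4.0, 0.0]
    tail = center - [4.0, 0.0]
    return make_track(center, t=t, nose=nose, tail=tail)
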