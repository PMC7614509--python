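import numpy as np
import pytest

from gcsearch.calibration import MotilityModel
from gcsearch.tracks_io import Track, TrackSet


@pytest.fixture
def toy_trackset() -> TrackSet:
    """Two short tracks at 30-s spacing with simple geometry."""
    t = np.arange(5) * 30.0
    straight = Track("a", t, np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)]))
    lpath = Track(
        "b",
        np.arange(3) * 30.0,
        np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [3.0, 4.0, 0.0]]),
    )
    return TrackSet([straight, lpath], frame_interval=30.0)


@pytest.fixture
def default_model() -> MotilityModel:
    return MotilityModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230915)
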