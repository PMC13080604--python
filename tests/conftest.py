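import numpy as np
import pytest

from vibroscreen.synthetic import VibrationSpec, generate_video
from vibroscreen.video import VideoCube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cube(rng):
    """Small random video cube for oracle-equivalence checks."""
    frames = rng.uniform(50, 150, size=(64, 8, 8))
    return VideoCube(frames=frames, frame_rate=32.0)


@pytest.fixture
def tone_cube():
    """Pure 2 Hz tone at 32 fps for 10 s, every pixel, mild noise."""
    spec = VibrationSpec(frame_rate=32.0, duration=10.0, image_size=(8, 8),
                         components=[(2.0, 300.0, None)], noise_sd=0.2)
    return generate_video(spec, seed=42)
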