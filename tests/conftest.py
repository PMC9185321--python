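import numpy as np
import pytest

from fallgan.synthetic import NoiseParams, SceneParams
from fallgan.video_io import VideoClip


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scene32():
    return SceneParams(frame_size=32, seed=11)


@pytest.fixture
def no_noise():
    return NoiseParams()


def make_clip(n_frames=14, side=16, seed=0, labels=None, fps=25.0):
    rng = np.random.default_rng(seed)
    frames = rng.uniform(0.05, 1.0, size=(n_frames, side, side))
    return VideoClip(
        frames=frames,
        labels=labels,
        fps=fps,
        clip_id=f"random_{seed}",
        value_range=(0.0, 1.0),
    )
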