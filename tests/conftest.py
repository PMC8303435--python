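import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A small jitter-free clip with all three structures and known truth."""
    from hyotrack import PhantomSpec, make_phantom

    spec = PhantomSpec(frame_count=24, frame_size=(96, 96), coin_diameter_px=22.0,
                       motion_period_frames=20, jitter_px=0.0, noise_sd=0.01, seed=7)
    frames, truth = make_phantom(spec)
    return spec, frames, truth
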