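import numpy as np
import pytest

from hystsum import OperatorParams, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_params():
    """Operator parameters scaled for tiny test frames."""
    return OperatorParams(
        block_size=8,
        search_radius=4,
        entropy_window=9,
        gray_levels=64,
        closing_radius=2,
        pyramid_levels=2,
    )


@pytest.fixture(scope="session")
def small_spec():
    """A 60-frame synthetic sequence: 3 dwells of 10 frames, glare on pans."""
    return SyntheticSpec(
        n_frames=60, height=80, width=96, n_events=3, dwell_length=10, seed=7
    )


@pytest.fixture(scope="session")
def small_video(small_spec):
    return generate(small_spec)


def random_rgb(rng, h, w):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
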