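import numpy as np
import pytest

from matriscope.synthetic import FiberImage, GeneratorParams, generate_image


@pytest.fixture(scope="session")
def small_params() -> GeneratorParams:
    """Quarter-size frames (2x2 grid of 104x120 tiles) for fast tests."""
    return GeneratorParams(height=208, width=240, n_fibers=8, n_steps=80)


@pytest.fixture(scope="session")
def small_image(small_params) -> FiberImage:
    return generate_image("network_sparse", seed=11, params=small_params)


@pytest.fixture(scope="session")
def full_frame_image() -> FiberImage:
    """One default-size (1040x1440) frame."""
    return generate_image("long_fiber", seed=1)


def random_rgb(shape, seed=0):
    return np.random.default_rng(seed).random(shape, dtype=np.float32)
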