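import numpy as np
import pytest

from cellcut import GrayImage, generate, generate_scribbles, preset, scribble_seeds


@pytest.fixture
def bimodal_image():
    """10x10 image: 60 pixels at grey 50, 40 pixels at grey 200."""
    px = np.full(100, 50, dtype=np.int64)
    px[60:] = 200
    return GrayImage(px.reshape(10, 10))


@pytest.fixture
def ring_fixture():
    """One seeded boundary-ring image with interior-only scribble seeds."""

    def make(seed):
        params = preset("ring", seed)
        image, truth = generate(params)
        scribble = generate_scribbles(truth, 0.3, seed, erosion_radius=params.ring_width + 1)
        return image, truth, scribble_seeds(scribble, image)

    return make


@pytest.fixture
def two_block_image():
    """Left half bright (200), right half dark (50)."""
    px = np.full((8, 8), 50, dtype=np.int64)
    px[:, :4] = 200
    return GrayImage(px)
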