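import numpy as np
import pytest

from vesicoloc.imaging_io import ImageStack
from vesicoloc.synthetic_scene import SceneParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene_params():
    """A compact scene that generates quickly: 15 vesicles on 256x256."""
    return SceneParams(
        image_size_px=(256, 256),
        n_vesicles=15,
        nucleus_diameter_um=8.0,
        n_mito_filaments=5,
        seed=7,
    )


def make_stack8(planes: dict[str, np.ndarray], pixel_size_um: float = 0.1):
    """Assemble a single-z 8-bit ImageStack from named 2D planes."""
    names = list(planes)
    pixels = np.stack([np.asarray(planes[n], dtype=np.uint8) for n in names])
    return ImageStack(
        pixels=pixels[:, None, :, :],
        pixel_size_um=pixel_size_um,
        bit_depth=8,
        channel_names=names,
    )


def spot_image(shape, centers, sigma, amplitude, background=0.0):
    """Noise-free image of Gaussian spots; float64."""
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (x, y), a in zip(centers, np.broadcast_to(amplitude, (len(centers),))):
        img += a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return img
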