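import numpy as np
import pytest

from ctcdf.image_io import RasterImage
from ctcdf.synthetic import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A compact synthetic frame with tumor cells, blood cells and a halo."""
    params = SceneParams(
        height=192, width=192, n_tumor=2, n_blood=20, artifact_halos=1, seed=11
    )
    image, mask, objects = generate_scene(params)
    return image, mask, objects


@pytest.fixture
def random_image(rng):
    """An unstructured random RGB frame for fuzz-style checks."""
    return RasterImage(pixels=rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8))
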