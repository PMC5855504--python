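import numpy as np
import pytest

from dermlin.synthetic_data import SynthSpec, generate_lesion_dataset
from dermlin.types import BinaryMask, LesionImage


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_lesion_items():
    """Six synthetic lesion images (two per class) at the minimum side."""
    spec = SynthSpec(n_per_class=(2, 2, 2), image_side=64, seed=7)
    return generate_lesion_dataset(spec)


@pytest.fixture()
def random_image(rng):
    return LesionImage(pixels=rng.random((64, 64, 3)), image_id="rand")


@pytest.fixture()
def square_mask():
    m = np.zeros((5, 5), dtype=np.uint8)
    m[1:4, 1:4] = 1
    return BinaryMask(pixels=m, image_id="sq")
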