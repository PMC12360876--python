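import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from usmixaug import BinaryMask, GrayImage, LabeledSample, make_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom_corpus():
    """Small reusable phantom corpus: 6 labeled + 8 unlabeled, 48x48."""
    return make_dataset(6, 8, seed=123, height=48, width=48)


def random_pair(rng: np.random.Generator, size: int = 16):
    """A random labeled sample plus unlabeled partner of matching size."""
    image = GrayImage(rng.uniform(0.0, 1.0, (size, size)), source_id="L")
    mask = (rng.uniform(size=(size, size)) < 0.3).astype(np.uint8)
    labeled = LabeledSample(image=image, mask=BinaryMask(mask), source_id="L")
    unlabeled = GrayImage(rng.uniform(0.0, 1.0, (size, size)), source_id="U")
    return labeled, unlabeled


@pytest.fixture()
def rng():
    return np.random.default_rng(20250921)
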