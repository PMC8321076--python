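import numpy as np
import pytest
from hypothesis import settings

from dermtex import features, synthetic
from dermtex.imaging import GrayImage

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


def random_gray_patch(rng, shape=(6, 6), levels=8) -> GrayImage:
    """Integer-leveled random patch for texture tests."""
    return GrayImage(pixels=rng.integers(0, levels, size=shape),
                     levels=levels, normalized=False)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A modest two-class synthetic feature table shared across tests:
    30 images per class, 10 patches each -> 600 feature vectors."""
    out = tmp_path_factory.mktemp("small_synth")
    cfg = synthetic.default_config(seed=101, n_images_per_class=30,
                                   image_size=64)
    manifest = synthetic.generate_dataset(cfg, out)
    return features.extract_dataset(manifest, seed=101)
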