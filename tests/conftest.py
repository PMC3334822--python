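import numpy as np
import pytest

from bcmnorm import retina, synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ensemble():
    """Fast 64x64 synthetic ensemble with default statistics."""
    spec = synthetic.SyntheticImageSpec(n_images=4, size=64, seed=7)
    return synthetic.pink_noise_ensemble(spec)


@pytest.fixture(scope="session")
def filtered_images(small_ensemble):
    kernel = retina.build_dog_kernel()
    logged = retina.log_transform(small_ensemble)
    return [retina.filter_and_crop(im, kernel) for im in logged]


@pytest.fixture(scope="session")
def patchset(filtered_images):
    return retina.extract_patches(filtered_images, g=8, n_patches=200, seed=11)
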