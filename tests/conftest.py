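import numpy as np
import pytest

from skinmil import SyntheticSpec, generate_images, images_to_bags


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def benchmark_bags():
    """The layered-image benchmark featurized at p = 8, 10, 12.

    Built once per session: segmentation of 80 images dominates the suite's
    runtime, and the end-to-end tests only read from these datasets.
    """
    spec = SyntheticSpec(n_images=80, n_terms=4, noise_sd=0.02, seed=11)
    images, truth = generate_images(spec)
    return images_to_bags(images, truth.annotation, [8, 10, 12])


@pytest.fixture(scope="session")
def small_images():
    """A handful of layered images for segmentation-level tests."""
    spec = SyntheticSpec(n_images=4, n_terms=4, noise_sd=0.02, seed=5)
    images, truth = generate_images(spec)
    return images, truth
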