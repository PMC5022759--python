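import numpy as np
import pytest

from gaseg import (CSF, GM, WM, GAConfig, GrowConfig, PhantomSpec,
                   ReferenceSegmentation, generate_phantom)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """64x64 nested-ellipse phantom with zero noise and zero bias."""
    spec = PhantomSpec(shape=(64, 64), noise_sigma=0.0, rng_seed=11)
    image, ref = generate_phantom(spec)
    return spec, image, ref


@pytest.fixture(scope="session")
def noisy_phantom():
    """64x64 phantom at noise sigma 10 on the 0-255 intensity scale."""
    spec = PhantomSpec(shape=(64, 64), noise_sigma=10.0, rng_seed=12)
    image, ref = generate_phantom(spec)
    return spec, image, ref


def make_blob_fixture(noise_sigma=12.0, rng_seed=7):
    """8x8 three-blob image with known ground truth and mild noise.

    WM / GM / CSF occupy disjoint 3x3 blocks on a dark background; the
    candidate windows at the class-mean midpoints yield ~9 candidate
    seeds per class, small enough for exhaustive seed-combination search.
    """
    labels = np.zeros((8, 8), dtype=np.int32)
    labels[1:4, 1:4] = WM
    labels[1:4, 5:8] = GM
    labels[5:8, 1:4] = CSF
    means = np.array([0.0, 60.0, 120.0, 200.0])
    rng = np.random.default_rng(rng_seed)
    image = means[labels] + rng.normal(0.0, noise_sigma, labels.shape)
    ref = ReferenceSegmentation.from_label_map(labels)
    return image, ref


@pytest.fixture()
def blob_fixture():
    return make_blob_fixture()


@pytest.fixture()
def grow_cfg():
    return GrowConfig()


@pytest.fixture()
def small_ga_cfg():
    return GAConfig(population_size=12, generations=15, stall_generations=5,
                    rng_seed=0)
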