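import numpy as np
import pytest

from histotex import LabeledImage, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset() -> list[LabeledImage]:
    """Eight small, well-separated synthetic images (2 per class)."""
    return generate_dataset(
        SyntheticSpec(n_per_class=(2, 2, 2, 2), image_size=(64, 64), separability=1.0, seed=11)
    )


@pytest.fixture(scope="session")
def separable_dataset() -> list[LabeledImage]:
    """Ten images per class, maximally separable; used for learning checks."""
    return generate_dataset(
        SyntheticSpec(n_per_class=(10, 10, 10, 10), image_size=(64, 64), separability=1.0, seed=23)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_quantized_images(n: int, shape=(16, 16), G: int = 8, seed: int = 0):
    """Seeded batch of random quantized images for oracle comparisons."""
    from histotex import QuantizedImage

    rng = np.random.default_rng(seed)
    return [
        QuantizedImage(levels=rng.integers(0, G, size=shape), G=G, source_id=f"r{i}")
        for i in range(n)
    ]
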