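import numpy as np
import pytest

from apneafusion import SynthConfig, gen_dataset, gen_segment


@pytest.fixture(scope="session")
def synth_pair():
    """One normal and one apneic synthetic segment (default conditions)."""
    return gen_segment("N", SynthConfig(seed=11)), gen_segment("A", SynthConfig(seed=12))


@pytest.fixture(scope="session")
def small_dataset():
    """Six segments per class, default generator conditions."""
    segments, manifest = gen_dataset(6, SynthConfig(seed=5))
    return segments, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_separable_images(n_per_class: int, side: int, seed: int):
    """Tiny two-class image set: energy concentrated in the top vs bottom
    half, with enough noise that the task is non-trivial but learnable."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for label in ["N"] * n_per_class + ["A"] * n_per_class:
        img = rng.uniform(0.0, 0.3, size=(side, side, 3))
        band = slice(0, side // 2) if label == "N" else slice(side // 2, side)
        img[band] += 0.5
        images.append(np.clip(img, 0, 1))
        labels.append(label)
    return np.asarray(images, dtype=np.float32), np.asarray(labels)
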