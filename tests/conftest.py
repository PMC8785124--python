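import numpy as np
import pytest

import unifocal as uf


def make_random_batch(rng, batch=2, shape=(4, 4), num_classes=2):
    """Softmax probability map + matching one-hot labels."""
    logits = rng.normal(size=(batch, *shape, num_classes))
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    p = e / e.sum(axis=-1, keepdims=True)
    labels = rng.integers(0, num_classes, size=(batch, *shape))
    return p, uf.one_hot_encode(labels, num_classes)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_batch(rng):
    return make_random_batch(rng)


@pytest.fixture
def sixteen_position_fixture():
    """p foreground = 0.5 everywhere, truth foreground on 4 of 16 positions.

    Soft counts for the foreground class: tp=2, fp=6, fn=2.
    """
    p = np.full((1, 4, 4, 2), 0.5)
    labels = np.zeros((1, 4, 4), dtype=int)
    labels[0, 0, :] = 1
    return p, uf.one_hot_encode(labels, 2)


@pytest.fixture
def probability_grid_3x3():
    """Fixed, non-degenerate 3x3 binary probability grid for oracle sweeps."""
    fg = np.linspace(0.05, 0.95, 9).reshape(1, 3, 3)
    return np.stack([1.0 - fg, fg], axis=-1)


def all_binary_masks_3x3():
    """All 512 binary ground-truth masks on the 3x3 grid, as one-hot arrays."""
    masks = []
    for bits in range(512):
        flat = np.array([(bits >> k) & 1 for k in range(9)])
        masks.append(uf.one_hot_encode(flat.reshape(1, 3, 3), 2))
    return masks
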