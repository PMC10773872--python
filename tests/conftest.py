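import numpy as np
import pytest

from glandseg import synthetic_data, training


def make_patch_set(n: int, size: int = 48, seed: int = 0):
    """Mixed benign/GP3/GP4 synthetic patches with masks (deterministic)."""
    rng = np.random.default_rng(seed)
    kinds = ("benign", "gp3_like", "gp4_like")
    images, masks = [], []
    for _ in range(n):
        kind = kinds[int(rng.integers(3))]
        style = synthetic_data.GlandStyle.preset(
            kind, crowding=float(rng.uniform(0.15, 0.45))
        )
        pair = synthetic_data.generate_patch_pair(
            style, size, int(rng.integers(2 ** 31))
        )
        images.append(pair.image)
        masks.append(pair.mask)
    return np.stack(images), np.stack(masks)


@pytest.fixture(scope="session")
def small_patch_set():
    """48 mixed 48x48 patches shared by cheap tests."""
    return make_patch_set(48, size=48, seed=11)


@pytest.fixture(scope="session")
def tiny_streams():
    """Train/val batch streams over 32/8 tiny (32x32) patches."""
    images, masks = make_patch_set(40, size=32, seed=5)
    tr = training.BatchStream(images[:32], masks[:32], batch_size=8,
                              shuffle=True, seed=0)
    va = training.BatchStream(images[32:], masks[32:], batch_size=8,
                              shuffle=False, seed=0)
    return tr, va
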