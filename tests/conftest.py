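import numpy as np
import pytest

import lungreg
from lungreg import experiments as ex


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A fast phantom configuration for unit tests."""
    return lungreg.PhantomConfig(image_size=48, n_frames=5, breathing_amplitude=0.15, seed=11)


@pytest.fixture(scope="session")
def small_sequence(small_config):
    return lungreg.generate_breathing_sequence(small_config)


@pytest.fixture(scope="session")
def random_mask_pairs(rng):
    """Blob-like binary mask pairs for metric oracle checks."""
    pairs = []
    for _ in range(100):
        h = int(rng.integers(8, 33))
        w = int(rng.integers(8, 33))

        def blob():
            m = np.zeros((h, w), np.uint8)
            for _ in range(int(rng.integers(1, 4))):
                cy, cx = rng.integers(0, h), rng.integers(0, w)
                r = int(rng.integers(2, max(3, min(h, w) // 2)))
                yy, xx = np.ogrid[:h, :w]
                m[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 1
            if m.sum() == 0:
                m[h // 2, w // 2] = 1
            return m

        pairs.append((blob(), blob()))
    return pairs


@pytest.fixture(scope="session")
def trained_pipelines():
    """Full desk-scale pipelines for seeds 1-3 (trained once per session)."""
    return {seed: ex.train_full_pipeline(seed=seed) for seed in (1, 2, 3)}
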