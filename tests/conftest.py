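import numpy as np
import pytest

from protoslide.synthetic import (
    IDENTITY_SCANNER,
    default_tissue_classes,
    generate_patch,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    """A uniformly random uint8 patch (worst case for round-trip bounds)."""
    return rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)


@pytest.fixture
def random_patches(rng):
    return rng.integers(0, 256, (100, 16, 16, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def tissue_patch():
    """One rendered synthetic tissue patch in the base domain."""
    cls = default_tissue_classes()[-1]  # tumor: dense, strongly stained
    return generate_patch(cls, IDENTITY_SCANNER, 64, seed=7).pixels
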