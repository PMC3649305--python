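import numpy as np
import pytest

from spectspine import (
    PhantomSpec,
    extract_spine,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_truth():
    """Default noisy phantom, seed 1 (the canonical study condition)."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def default_result(default_truth):
    return extract_spine(default_truth.volume)


@pytest.fixture(scope="session")
def spine_only_truth():
    """Noise-free, blur-free phantom without ribs/kidneys/bladder."""
    return generate_phantom(PhantomSpec(
        seed=1, ribs=False, kidneys=False, bladder=False,
        noise="none", psf_sigma=0.0))


@pytest.fixture(scope="session")
def spine_only_result(spine_only_truth):
    return extract_spine(spine_only_truth.volume)


@pytest.fixture(scope="session")
def gap0_truth():
    """Ectopic-kidney phantom: kidneys touch the spine (failure mode)."""
    return generate_phantom(PhantomSpec(seed=1, kidney_spine_gap=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
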