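import numpy as np
import pytest

from segsense import (
    GrayImage,
    LabelMask,
    PhantomSpec,
    Sample,
    build_registry,
    make_phantom,
    threshold_oracle,
)


@pytest.fixture(scope="session")
def phantom_sample() -> Sample:
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_sample() -> Sample:
    return make_phantom(PhantomSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def oracle():
    return threshold_oracle(PhantomSpec())


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture
def asym3x3() -> np.ndarray:
    """A 3x3 array with no nontrivial dihedral symmetry."""
    return np.arange(9, dtype=float).reshape(3, 3) / 8.0


@pytest.fixture
def asym_sample(asym3x3) -> Sample:
    mask = LabelMask(np.array([[0, 1, 0], [2, 0, 3], [0, 0, 1]]))
    return Sample(GrayImage(asym3x3), mask)
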