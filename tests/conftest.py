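import numpy as np
import pytest

from drmm import AcquisitionGrid


@pytest.fixture(scope="session")
def grid16() -> AcquisitionGrid:
    """The exemplar 4x4 (TE, b) protocol: 16 points per voxel."""
    return AcquisitionGrid.from_product()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def rician_corrupt(
    clean: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude of a complex signal with iid Gaussian channel noise."""
    n1 = rng.normal(0.0, sigma, clean.shape)
    n2 = rng.normal(0.0, sigma, clean.shape)
    return np.sqrt((clean + n1) ** 2 + n2**2)
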