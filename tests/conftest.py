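import numpy as np
import pytest

from voroperf.containers import LungMask, VolumeGrid


def ellipsoid_mask(
    shape=(40, 40, 40),
    left=((12.0, 20.0, 20.0), (7.0, 9.0, 12.0)),
    right=((28.0, 20.0, 20.0), (7.0, 9.0, 12.0)),
    spacing=(1.0, 1.0, 1.0),
) -> LungMask:
    labels = np.zeros(shape, dtype=np.int16)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    for lab, (center, axes) in ((1, left), (2, right)):
        q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
        labels[q <= 1.0] = lab
    return LungMask(labels, spacing)


@pytest.fixture(scope="session")
def two_lung_mask() -> LungMask:
    return ellipsoid_mask()


@pytest.fixture(scope="session")
def small_case(two_lung_mask):
    """Deterministic smooth positive perfusion map on the session mask."""
    rng = np.random.default_rng(42)
    from scipy.ndimage import gaussian_filter

    base = 1.0 + 0.3 * gaussian_filter(rng.standard_normal(two_lung_mask.shape), 3.0)
    base = np.clip(base, 0.05, None)
    return VolumeGrid(base, two_lung_mask.spacing), two_lung_mask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
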