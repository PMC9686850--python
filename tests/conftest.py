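import numpy as np
import pytest

from dermrad.cohort import CohortSpec, generate_cohort
from dermrad.grids import ImageVolume, RoiMask


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small deterministic phantom cohort shared across tests."""
    spec = CohortSpec(n_patients=12, n_rd2plus=8, grid_shape=(32, 32, 20), seed=11)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def textured_roi():
    """A non-degenerate textured ROI on a small grid."""
    rng = np.random.default_rng(5)
    arr = rng.normal(40.0, 12.0, size=(14, 14, 6))
    image = ImageVolume(arr, (4.0, 4.0, 5.0))
    mask = np.zeros(arr.shape, bool)
    mask[2:12, 2:12, 1:5] = True
    return image, RoiMask("PTV_100PD", mask)
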