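import numpy as np
import pytest

from voxdose.grid import VolumeGrid
from voxdose.synth import CohortConfig, generate_cohort, make_reference

SMALL_SHAPE = (48, 48, 76)
SMALL_SPACING = (1.27, 1.27, 1.0)


@pytest.fixture(scope="session")
def small_ref():
    return make_reference(SMALL_SHAPE, SMALL_SPACING, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """24 patients on a compact grid; shared across read-only tests."""
    cfg = CohortConfig(shape=SMALL_SHAPE, spacing=SMALL_SPACING)
    return generate_cohort(24, cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_box_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    """Axis-aligned box mask with inclusive-exclusive [lo, hi) bounds."""
    vals = np.zeros(shape, dtype=np.uint8)
    vals[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] = 1
    return VolumeGrid(vals, spacing, origin)


@pytest.fixture()
def box_mask_factory():
    return make_box_mask
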