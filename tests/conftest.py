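import numpy as np
import pytest

from myoradiomics.cohort import CohortSpec, QuantitativeMap, RoiMask, generate_cohort
from myoradiomics.preprocess import DiscretizedRoi


def make_droi(levels, spacing=(1.0, 1.0), bin_width=1.0) -> DiscretizedRoi:
    """DiscretizedRoi from an integer level grid (0 = background)."""
    levels = np.asarray(levels, dtype=np.int64)
    mask = levels > 0
    return DiscretizedRoi(levels, mask, int(levels.max()), spacing, bin_width)


def random_droi(rng: np.random.Generator, max_side: int = 12, max_ng: int = 6) -> DiscretizedRoi:
    """Random small ROI with random levels; always at least one pixel."""
    shape = (rng.integers(2, max_side + 1), rng.integers(2, max_side + 1))
    mask = rng.random(shape) < rng.uniform(0.4, 0.9)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    ng = int(rng.integers(1, max_ng + 1))
    levels = np.where(mask, rng.integers(1, ng + 1, shape), 0)
    return make_droi(levels)


@pytest.fixture(scope="session")
def small_cohort():
    """Five-subject T1 cohort shared by the slower integration tests."""
    return generate_cohort(CohortSpec.t1_default(n_subjects=5, seed=11))


@pytest.fixture()
def flat_map():
    """A 12x12 map with a 6x6 square ROI of constant value."""
    values = np.full((12, 12), 800.0)
    mask = np.zeros((12, 12), dtype=bool)
    mask[3:9, 3:9] = True
    return QuantitativeMap(values, (2.0, 2.0), "T1", "flat"), RoiMask(mask)
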