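import numpy as np
import pytest

from immunorad.synthetic import CohortConfig, generate_cohort
from immunorad.volumes import CTVolume, ROIMask


def make_volume(arr, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(arr, dtype=np.float64), spacing)


def make_mask(arr, spacing=(1.0, 1.0, 1.0)):
    return ROIMask(np.asarray(arr), spacing)


def full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return ROIMask(np.ones(shape, dtype=np.uint8), spacing)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten synthetic patients with images, shared across tests."""
    return generate_cohort(CohortConfig(n_patients=10, seed=11))


@pytest.fixture(scope="session")
def one_patient(small_cohort):
    return small_cohort[0]


def random_voi(rng, max_shape=(4, 4, 4), n_levels=4):
    """Small random quantized VOI (levels + mask) for brute-force oracles."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    fg = rng.random(shape) < 0.7
    if not fg.any():
        fg.flat[0] = True
    levels[~fg] = 0
    return levels, fg
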