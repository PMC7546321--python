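import numpy as np
import pytest

from gfcpipe.niio import GrayMatterMask, TimeSeriesMatrix, Volume4D
from gfcpipe.simulate import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """Tiny 4D volume: 6x6x6 grid, 20 frames, TR 2 s."""
    data = rng.normal(size=(6, 6, 6, 20))
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return Volume4D(data=data, affine=affine, tr=2.0)


@pytest.fixture
def ball_mask():
    """Spherical mask on the 6x6x6 grid."""
    coords = np.indices((6, 6, 6), dtype=float)
    dist = np.sqrt(((coords - 2.5) ** 2).sum(axis=0))
    return GrayMatterMask(data=dist <= 2.5, affine=np.diag([3.0, 3.0, 3.0, 1.0]))


@pytest.fixture
def random_ts(rng):
    """Random frames x voxels matrix wrapped as a TimeSeriesMatrix."""
    values = rng.normal(size=(40, 12))
    voxel_index = np.column_stack(
        np.unravel_index(np.arange(12), (3, 2, 2), order="F")
    )
    return TimeSeriesMatrix(values=values, voxel_index=voxel_index, tr=2.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small synthetic cohort shared by read-only tests (session scope)."""
    spec = CohortSpec(
        n_patients=4, n_controls=4, grid_shape=(12, 12, 12), n_volumes=60,
        seed=7,
    )
    return generate_cohort(spec)
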