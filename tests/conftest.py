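import numpy as np
import pytest

from cordflow.datatypes import SpatialProfile
from cordflow.synthetic import GroundTruthProfile, SceneConfig, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_truth():
    return GroundTruthProfile()


@pytest.fixture(scope="session")
def small_scene_config():
    """A reduced scene for fast rendering tests (6.4 x 3.2 mm field)."""
    return SceneConfig(
        shape=(64, 128),
        upper_border_row=10.0,
        lower_border_row=54.0,
        axial_row=32,
    )


@pytest.fixture
def small_scene(small_scene_config, default_truth):
    return make_scene(small_scene_config, default_truth, seed=42)


def profile_from_values(centers, values, counts=None, bin_width=0.1, units="AU"):
    centers = np.asarray(centers, dtype=float)
    values = np.asarray(values, dtype=float)
    if counts is None:
        counts = np.ones(centers.size, dtype=int)
    return SpatialProfile(
        bin_centers=centers,
        index_values=values,
        bin_pixel_counts=counts,
        bin_width=bin_width,
        units=units,
    )
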