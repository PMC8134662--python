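import numpy as np
import pytest

from strokenest.atlas import make_toy_atlas
from strokenest.simulate import (
    default_atlas,
    default_config_for_atlas,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_atlas():
    """16-cube atlas with 3 GM regions and 1 WM tract (fast unit fixture)."""
    return make_toy_atlas((16, 16, 16), n_gm_regions=3, n_wm_tracts=1, seed=2)


@pytest.fixture(scope="session")
def cohort200():
    """One n=200 cohort at the pipeline defaults, shared across tests."""
    atlas = default_atlas(seed=0)
    config = default_config_for_atlas(atlas, n_patients=200, seed=0)
    return simulate_cohort(config, atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
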