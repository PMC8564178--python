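import numpy as np
import pytest

from neurocouple.synthetic import CohortSpec, generate_atlas


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Compact cohort used across tests: 12^3 grid, 8 regions, short series."""
    return CohortSpec(
        group_sizes={"mild": 6, "moderate": 5, "severe": 6},
        atlas_shape=(12, 12, 12),
        n_regions=8,
        n_communities=2,
        n_frames=60,
        asl_n_pairs=8,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    atlas, mask = generate_atlas(small_spec)
    return atlas, mask


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
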