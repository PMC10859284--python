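import numpy as np
import pytest

from morphnet.synthetic import SyntheticDesign, make_atlas, make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(
        grid_shape=(12, 12, 12), n_roi=10, n_low=5, n_high=5, seed=11, noise_sd=0.05
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return make_cohort(small_design)


@pytest.fixture(scope="session")
def small_atlas(small_design):
    return make_atlas(small_design)


def random_adjacency(n, density, rng):
    a = np.zeros((n, n), dtype=bool)
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    a[iu[0][mask], iu[1][mask]] = True
    return a | a.T
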