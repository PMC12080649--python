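import numpy as np
import pytest

import brainpad as bp


@pytest.fixture(scope="session")
def geometry60():
    return bp.make_geometry(60, seed=0)


@pytest.fixture(scope="session")
def geometry100():
    return bp.make_geometry(100, seed=3)


@pytest.fixture(scope="session")
def small_dataset(geometry60):
    """Multi-site cohort with an injected thinning cluster, for reuse."""
    cohort = bp.make_cohort(120, 80, n_sites=4, seed=2)
    features, truth = bp.simulate_thickness(
        cohort, geometry60, seed=3, n_age_regions=30, n_affected=8
    )
    return cohort, features, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
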