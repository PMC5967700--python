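import numpy as np
import pytest
from hypothesis import settings

from neuroctrl import CohortSpec, generate_cohort, twin_symmetric_matrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """Three connected 10-node subjects from one modular base."""
    return generate_cohort(CohortSpec(n_subjects=3, N=10, density=0.4,
                                      n_modules=2, seed=7))


@pytest.fixture(scope="session")
def small_W(small_cohort):
    return small_cohort[0].W


@pytest.fixture(scope="session")
def twin_matrix():
    """Engineered network with a structurally twin node pair (0, 1)."""
    return twin_symmetric_matrix(8, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
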