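import numpy as np
import pandas as pd
import pytest

import seqmorph as sm
from seqmorph import surface_stats as ss


@pytest.fixture(scope="session")
def mesh():
    """Shared icosphere test-bed mesh (2562 vertices, ~100 mm diameter)."""
    return ss.default_mesh()


@pytest.fixture(scope="session")
def cohort18():
    return sm.simulate_cohort(18, seed=101)


@pytest.fixture(scope="session")
def ratings18(cohort18):
    return sm.simulate_ratings(cohort18, seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _null_ratings(n_subjects=18, trials=21, seed=0):
    """Ratings with zero discriminability: condition carries no information."""
    cohort = sm.simulate_cohort(n_subjects, seed=seed)
    cohort = cohort.assign(discrimination=1e-12)  # alpha must stay positive
    design = sm.RatingDesign(trials_per_condition=trials)
    return cohort, sm.simulate_ratings(cohort, design, seed=seed + 1)


@pytest.fixture(scope="session")
def make_null_ratings():
    return _null_ratings
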