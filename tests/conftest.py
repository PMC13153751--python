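import numpy as np
import pytest

from gripsense.features import build_feature_tables
from gripsense.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_participants=3, n_days=2, sets_per_day=3, rng_seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return build_feature_tables(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
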