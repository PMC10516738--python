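import numpy as np
import pytest

from hnart import CohortSpec, PhantomSpec, generate_feature_table, generate_phantom_series


@pytest.fixture(scope="session")
def small_phantom():
    """A 5-fraction phantom series with its registration records and truth."""
    spec = PhantomSpec(n_fractions=5, seed=101)
    images, records, window, truth = generate_phantom_series(spec)
    return spec, images, records, window, truth


@pytest.fixture(scope="session")
def cohort_table():
    """Default-effect synthetic cohort at the study's size."""
    return generate_feature_table(CohortSpec(seed=17))


@pytest.fixture(scope="session")
def null_table():
    """Cohort with every feature-label association removed."""
    return generate_feature_table(CohortSpec(n_patients=200, null_mode=True, seed=17))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
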