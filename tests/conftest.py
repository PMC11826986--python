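import numpy as np
import pytest

from biovad.cohort import SubjectProfile, simulate_cohort
from biovad.protocol import make_default_protocol


@pytest.fixture(scope="session")
def schedule():
    return make_default_protocol()


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile()


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic subjects, fixed seed; shared across test modules."""
    return list(simulate_cohort(6, seed=42))


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    """Per-method feature tables for the six-subject cohort."""
    from biovad.pipeline import METHODS, cohort_feature_table

    return {m: cohort_feature_table(small_cohort, m) for m in METHODS}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
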