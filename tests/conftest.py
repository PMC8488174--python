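import numpy as np
import pytest

from bonenet import CohortSpec, generate_cohort, mouse_60min_schedule


@pytest.fixture(scope="session")
def schedule():
    return mouse_60min_schedule()


@pytest.fixture(scope="session")
def default_cohort(schedule):
    """One default five-mouse cohort, shared across read-only tests."""
    return generate_cohort(CohortSpec(seed=0), schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
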