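import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (45 PG + 33 CP, 200 trials), shared."""
    from twostep import sample_cohort

    return sample_cohort(seed=0)


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    from twostep import apply_engagement_filters

    filtered, _ = apply_engagement_filters(default_cohort)
    return filtered


@pytest.fixture(scope="session")
def lagged_table(filtered_cohort):
    from twostep import build_lagged_table

    return build_lagged_table(filtered_cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
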