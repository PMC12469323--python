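import numpy as np
import pytest

from varstep import SchedulePolicy, SearchPolicy, builtin_fixtures


@pytest.fixture(scope="session")
def default_schedule():
    return SchedulePolicy(km=0.005)


@pytest.fixture(scope="session")
def default_search_policy():
    return SearchPolicy()


@pytest.fixture(scope="session")
def fixtures_error():
    """Built-in tabulated objectives that fail loudly on off-table queries."""
    return builtin_fixtures(missing_policy="error")


@pytest.fixture(scope="session")
def fixtures_nearest():
    return builtin_fixtures(missing_policy="nearest")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
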