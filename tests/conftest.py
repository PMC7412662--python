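import pytest
from hypothesis import settings

from gistcea import ParameterSet, run_cohort
from gistcea.fixtures import default_life_table

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture()
def base_params():
    return ParameterSet()


@pytest.fixture(scope="session")
def base_outcomes(life_table):
    """Both strategies at the base case (shared across tests)."""
    params = ParameterSet()
    return {s: run_cohort(s, params, life_table) for s in ("UAPR", "CIUP")}
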