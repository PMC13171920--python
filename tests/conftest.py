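import warnings

import pytest
from hypothesis import settings as hypothesis_settings

from megsni import default_cohort_scenario, generate_cohort

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

# MixedLM emits benign convergence chatter on small strata; keep test output clean
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-preset cohort draw shared across tests (seed frozen)."""
    return generate_cohort(default_cohort_scenario(), seed=1)


@pytest.fixture(scope="session")
def cohort_table(default_cohort):
    return default_cohort.table
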