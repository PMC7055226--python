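import pytest

from cgtcal import CohortConfig, build_model_tables, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort: 58 children, 29 per arm."""
    cohort, truth = simulate_cohort(CohortConfig(seed=1))
    return cohort


@pytest.fixture(scope="session")
def model_tables(default_cohort):
    return build_model_tables(default_cohort)
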