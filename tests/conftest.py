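import pytest

from somascape.fixtures import reference_signatures, table4_records
from somascape.io import expand_carriers
from somascape.synth import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def reference():
    return reference_signatures()


@pytest.fixture(scope="session")
def table4_calls():
    """The recurrent-variant table expanded to one call per carrier."""
    return expand_carriers(table4_records())


@pytest.fixture(scope="session")
def default_cohort(reference):
    """One seeded 50-patient cohort under the default study conditions."""
    return simulate_cohort(CohortConfig(n_samples=50, seed=7), reference)
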