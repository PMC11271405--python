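import pytest

from pgtflow.endpoints import derive_endpoints
from pgtflow.fixtures import make_fixture
from pgtflow.model import AnalysisConfig


@pytest.fixture(scope="session")
def printed_cohort():
    return make_fixture("printed_counts")


@pytest.fixture(scope="session")
def printed_config():
    return AnalysisConfig(cutoff_day=1600)


@pytest.fixture(scope="session")
def printed_endpoints(printed_cohort, printed_config):
    records, sets = derive_endpoints(printed_cohort, printed_config)
    return records, sets
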