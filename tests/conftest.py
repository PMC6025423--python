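import pandas as pd
import pytest
from hypothesis import settings

from mossmetal.data import COLUMNS, ConcentrationTable
from mossmetal.synth import load_profile, make_fixture

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lownoise():
    """The pinned low-noise two-factor survey fixture."""
    return make_fixture("two-factor-lownoise")


@pytest.fixture(scope="session")
def default_profile():
    return load_profile("default")


def mktable(records) -> ConcentrationTable:
    """Build a table from (site, medium, species, replicate, element, conc) tuples."""
    return ConcentrationTable(pd.DataFrame(records, columns=COLUMNS))


@pytest.fixture
def table_builder():
    return mktable
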