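import pytest

from dqrisk import default_serotype_table, table1_fixture


@pytest.fixture(scope="session")
def serotable():
    return default_serotype_table()


@pytest.fixture(scope="session")
def table1_cohort():
    return table1_fixture()
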