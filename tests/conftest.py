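import pytest

from glycowin import fixtures


@pytest.fixture(scope="session")
def reference_model():
    return fixtures.reference_window_model()


@pytest.fixture(scope="session")
def fetuin_records():
    return fixtures.fetuin_assignments()


@pytest.fixture(scope="session")
def inventory():
    return fixtures.glycopeptide_inventory()
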