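import pytest

from endodiv import load_fixture, load_fixture_frame


@pytest.fixture(scope="session")
def table1():
    """Packaged isolate inventory (one record per morphospecies per tissue)."""
    return load_fixture("table1_isolates")


@pytest.fixture(scope="session")
def reconstructed():
    """Inventory carrying index-consistent reconstructed colony counts."""
    return load_fixture("reconstructed_abundances")


@pytest.fixture(scope="session")
def table3():
    """Published per-plant index values, as printed."""
    return load_fixture_frame("table3_indices")
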