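import pytest

from netpharm.pipeline import load_bundled_tables


@pytest.fixture(scope="session")
def tables():
    """(decoction components, plasma features) from the bundled tables."""
    return load_bundled_tables()


@pytest.fixture(scope="session")
def decoction(tables):
    return tables[0]


@pytest.fixture(scope="session")
def plasma(tables):
    return tables[1]
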