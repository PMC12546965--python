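import pytest

from pouchcea.params import load_defaults
from pouchcea.primary import build_primary
from pouchcea.secondary import build_secondary


@pytest.fixture(scope="session")
def primary_ps():
    return load_defaults("primary")


@pytest.fixture(scope="session")
def secondary_ps():
    return load_defaults("secondary")


@pytest.fixture(scope="session")
def primary_models(primary_ps):
    """(probiotic, no prophylaxis) pair, base variant."""
    return build_primary(primary_ps)


@pytest.fixture(scope="session")
def secondary_models(secondary_ps):
    return build_secondary(secondary_ps)
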