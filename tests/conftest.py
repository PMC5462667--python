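import pytest

from fgscan import builtin_panel, random_molecules


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture(scope="session")
def corpus200():
    """Deterministic random small-molecule corpus shared across tests."""
    return random_molecules(200, seed=11)
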