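import pytest

from wgacompare.simulate import MutationConfig, generate_ancestor


@pytest.fixture(scope="session")
def small_ancestor():
    """200 kb x 2 chromosomes with 20 genes; shared across tests."""
    return generate_ancestor(2, 200_000, 20, gc=0.4, seed=7)


@pytest.fixture
def empty_config():
    return MutationConfig()
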