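import pytest

from taxograph.fixtures import FixtureSpec, gen_fixture


@pytest.fixture(scope="session")
def clean_fixture():
    """A medium clean fixture graph + manifest (shared, read-only)."""
    return gen_fixture(FixtureSpec(seed=11))


@pytest.fixture()
def clean_graph(clean_fixture):
    graph, _ = clean_fixture
    return graph
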