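import pytest

from ppiminer.fixtures import FixtureSpec, fig4_fixture, generate_corpus


@pytest.fixture(scope="session")
def fig4():
    return fig4_fixture()


@pytest.fixture(scope="session")
def small_corpus():
    """A 200-sentence synthetic corpus for fast module-level tests."""
    return generate_corpus(FixtureSpec(n_sentences=200, seed=7))
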