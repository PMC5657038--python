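import pytest

from nemoprofile import fixtures


@pytest.fixture
def f9():
    return fixtures.fixture_f9()


@pytest.fixture
def k4():
    return fixtures.complete_graph(4)


@pytest.fixture
def triangle():
    return fixtures.complete_graph(3)
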