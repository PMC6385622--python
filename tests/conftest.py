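import pytest

from hybridph import build_an, build_network, load_fixture
from hybridph.brn import Gene, Interaction, InteractionGraph


@pytest.fixture(scope="session")
def cascade():
    return load_fixture("toy-cascade")


@pytest.fixture(scope="session")
def oscillator():
    return load_fixture("toy-oscillator")


@pytest.fixture(scope="session")
def oscillator_constant_p():
    """Oscillator topology with p constant (not an input): the minimal
    published transition list, for stable-state analysis."""
    return InteractionGraph(
        [Gene("p", 1), Gene("q", 1), Gene("r", 1)],
        [Interaction("p", "r", 1, "+"), Interaction("q", "r", 1, "+"),
         Interaction("r", "q", 1, "-")],
        {"q": "!r", "r": "p & q"},
    )


@pytest.fixture(scope="session")
def phage():
    return load_fixture("phage-lambda")


@pytest.fixture(scope="session")
def oscillator_an(oscillator):
    return build_an(oscillator)


@pytest.fixture(scope="session")
def cascade_an(cascade):
    return build_an(cascade)


@pytest.fixture(scope="session")
def phage_an(phage):
    return build_an(phage)


@pytest.fixture(scope="session")
def oscillator_net(oscillator_an):
    return build_network(oscillator_an)


@pytest.fixture(scope="session")
def phage_net(phage_an):
    return build_network(phage_an)
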