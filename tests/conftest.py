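import pytest

from brnkit import builtin_model, build_state_graph
from brnkit.state_graph_analysis import QualitativeCycle

#: The homeostatic 10-state cycle of the mTOR model, in the order
#: (PI3K, PTEN, mTORC2, Akt, mTORC1, FOXO).
MTOR_CYCLE_STATES = [
    (1, 1, 1, 0, 0, 1), (1, 1, 1, 1, 0, 1), (1, 1, 1, 1, 0, 0),
    (1, 1, 1, 1, 1, 0), (0, 1, 1, 1, 1, 0), (0, 1, 1, 0, 1, 0),
    (0, 1, 0, 0, 1, 0), (0, 1, 0, 0, 1, 1), (0, 1, 0, 0, 0, 1),
    (0, 1, 1, 0, 0, 1),
]

#: The proliferative deadlock state of the mTOR model.
MTOR_STABLE_STATE = (1, 0, 1, 1, 1, 0)


@pytest.fixture(scope="session")
def mtor():
    return builtin_model()


@pytest.fixture(scope="session")
def mtor_graph(mtor):
    net, K = mtor
    return build_state_graph(net, K)


@pytest.fixture(scope="session")
def mtor_cycle():
    return QualitativeCycle.from_states(MTOR_CYCLE_STATES)
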