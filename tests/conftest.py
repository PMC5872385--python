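import pytest

from perfcolor import SignedGraph, toy_graph, toy_observations

# the two mutually-reversed optimal colorings, expanded to original nodes
TOY_COLORATION_1 = {
    "A": "down", "B": "down", "C": "down", "D": "down", "E": "down",
    "F": "down", "G": "up", "H": "up",
}
TOY_COLORATION_2 = {n: ("up" if c == "down" else "down")
                    for n, c in TOY_COLORATION_1.items()}

# the large component's membership with relative signs
TOY_COMPONENT_MAIN = {"A": 1, "B": 1, "C": 1, "D": 1, "E": 1, "F": 1,
                      "G": -1, "H": -1}


@pytest.fixture(scope="session")
def toy() -> SignedGraph:
    return toy_graph()


@pytest.fixture(scope="session")
def toy_obs():
    return toy_observations()


def single_edge_graph(sign: int = 1) -> SignedGraph:
    g = SignedGraph()
    g.add_edge("A", "B", sign)
    return g
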