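import networkx as nx
import pytest

from netprio.interactome import Interactome


@pytest.fixture
def triangle() -> Interactome:
    return Interactome.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def path_abc() -> Interactome:
    return Interactome.from_edges([("A", "B"), ("B", "C")])


def star(n_leaves: int, hub: str = "HUB") -> Interactome:
    return Interactome.from_edges((hub, f"L{i}") for i in range(n_leaves))


def random_connected(n: int, p: float, seed: int) -> Interactome:
    """Erdos-Renyi graph conditioned on connectivity (retries the seed)."""
    for offset in range(100):
        g = nx.gnp_random_graph(n, p, seed=seed + offset)
        if nx.is_connected(g):
            return Interactome.from_edges(
                (f"N{u:03d}", f"N{v:03d}") for u, v in g.edges
            )
    raise AssertionError("could not draw a connected graph")
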