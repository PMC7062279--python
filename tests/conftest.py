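import numpy as np
import pytest

from vasculome.core_graph import Centerline, VascularGraph


def straight_graph(nodes, edges, diameter=6.0, roles=None):
    """Build a VascularGraph from {id: (x,y,z)} and [(a, b)] or
    [(a, b, diameter)] with straight centerlines."""
    vg = VascularGraph()
    roles = roles or {}
    for nid, pos in nodes.items():
        vg.add_node(nid, pos, role=roles.get(nid, "none"))
    for e in edges:
        a, b = e[0], e[1]
        dia = e[2] if len(e) > 2 else diameter
        vg.add_edge(a, b, Centerline.straight(
            vg.node_position(a), vg.node_position(b), dia, n=3))
    vg.classify_node_kinds()
    return vg


def set_unit_conductances(vg, value=1.0):
    for _, _, d in vg.g.edges(data=True):
        d["conductance"] = value
        d["resistance"] = 1.0 / value
    return vg


def random_conductance_network(rng, n_nodes, extra_edges):
    """Connected random network with random positive conductances and
    straight unit-diameter centerlines."""
    nodes = {i: tuple(rng.uniform(0, 1000, 3)) for i in range(n_nodes)}
    order = rng.permutation(n_nodes)
    edges = [(int(order[i]), int(order[rng.integers(0, i)]))
             for i in range(1, n_nodes)]
    for _ in range(extra_edges):
        a, b = rng.integers(0, n_nodes, 2)
        if a != b:
            edges.append((int(a), int(b)))
    vg = straight_graph(nodes, edges)
    for _, _, d in vg.g.edges(data=True):
        c = float(rng.uniform(0.1, 10.0))
        d["conductance"] = c
        d["resistance"] = 1.0 / c
    return vg


@pytest.fixture(scope="session")
def default_network():
    """One default-parameter synthetic lobular network, shared across tests."""
    from vasculome.synthetic import SynthesisParams, generate_lobular_network

    return generate_lobular_network(SynthesisParams(seed=1))
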