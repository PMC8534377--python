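"""Shared fixtures: small analytic graphs and seeded synthetic networks."""

import numpy as np
import pytest

from funcstate import GeneratorSpec, WeightedNetwork, generate


@pytest.fixture(scope="session")
def two_node_net() -> WeightedNetwork:
    """Single unit-weight edge; Laplacian eigenvalues (0, 2)."""
    return WeightedNetwork(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture(scope="session")
def path3_net() -> WeightedNetwork:
    """Unit-weight path a-b-c; Laplacian eigenvalues (0, 1, 3)."""
    return WeightedNetwork.from_edges([("a", "b", 1.0), ("b", "c", 1.0)])


@pytest.fixture(scope="session")
def disjoint_edges_net() -> WeightedNetwork:
    """Two disjoint unit edges: 4 nodes, 2 components."""
    return WeightedNetwork.from_edges(
        [("a", "b", 1.0), ("c", "d", 1.0)], node_labels=["a", "b", "c", "d"]
    )


@pytest.fixture(scope="session")
def ws_net() -> WeightedNetwork:
    """Small-world ring, 60 nodes, mean degree 4, rewiring 0.05."""
    return generate(GeneratorSpec("watts_strogatz", 60, 11, {"k": 4, "p": 0.05}))


@pytest.fixture(scope="session")
def ba_tree() -> WeightedNetwork:
    """Preferential-attachment tree (m=1), 60 nodes."""
    return generate(GeneratorSpec("barabasi_albert", 60, 5, {"m": 1}))


@pytest.fixture(scope="session")
def fungal_like_net() -> WeightedNetwork:
    """Sparse tree with organized heterogeneous weights.

    A preferential-attachment tree whose cord weights grow with the endpoint
    degree product — thick trunk cords between hubs, thin peripheral tips —
    emulating conductance-weighted biological transport networks.
    """
    return generate(
        GeneratorSpec(
            "barabasi_albert",
            60,
            5,
            {"m": 1, "weights": {"distribution": "degree_product", "gamma": 1.0}},
        )
    )


@pytest.fixture(scope="session")
def small_fixture_nets(two_node_net, path3_net, ws_net, ba_tree) -> dict:
    """Connected fixtures spanning topologies, keyed by name."""
    rgg = generate(GeneratorSpec("random_geometric", 40, 3, {"radius": 0.3}))
    cliques = generate(GeneratorSpec("two_cliques", 8, 0, {"clique_size": 4}))
    return {
        "two_node": two_node_net,
        "path3": path3_net,
        "ws": ws_net,
        "ba_tree": ba_tree,
        "rgg": rgg,
        "two_cliques": cliques,
    }
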