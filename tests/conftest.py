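import itertools

import networkx as nx
import numpy as np
import pytest

from greenaccess.road_network import NetworkLocation, RoadNetwork
from greenaccess.synthetic_city import CityScenario, generate_city


@pytest.fixture
def lattice3() -> RoadNetwork:
    """3x3 road lattice, 500 m spacing (9 nodes, 12 edges)."""
    nodes = {j * 3 + i: (i * 500.0, j * 500.0) for j in range(3) for i in range(3)}
    edges = []
    for j in range(3):
        for i in range(3):
            n = j * 3 + i
            if i < 2:
                edges.append((n, n + 1))
            if j < 2:
                edges.append((n, n + 3))
    return RoadNetwork(nodes, edges)


@pytest.fixture(scope="session")
def small_city():
    """A compact generated city shared by read-only tests."""
    scenario = CityScenario(
        seed=7, extent=(3000.0, 3000.0), grid_spacing=250.0, n_subdistricts=8,
        n_residential=120, n_greenspaces=12, total_population=60_000,
        clustering=0.6,
    )
    return scenario, generate_city(scenario)


# ----------------------------------------------------------------------
# Brute-force shortest-path oracle
# ----------------------------------------------------------------------

def brute_force_distance(
    a: NetworkLocation,
    b: NetworkLocation,
    network: RoadNetwork,
    include_connectors: bool = True,
) -> float:
    """Exhaustive simple-path enumeration on an augmented graph where the
    two snapped locations are attached to their edges' endpoints."""
    g = nx.Graph()
    for u, v, length in network.edges:
        _add_min(g, u, v, length)
    for name, loc in (("__A__", a), ("__B__", b)):
        length = network.edges[loc.edge_id][2]
        _add_min(g, name, loc.u, loc.offset)
        _add_min(g, name, loc.v, length - loc.offset)
    if a.edge_id == b.edge_id:
        _add_min(g, "__A__", "__B__", abs(a.offset - b.offset))
    best = np.inf
    if nx.has_path(g, "__A__", "__B__"):
        for path in nx.all_simple_paths(g, "__A__", "__B__"):
            w = sum(g[u][v]["weight"] for u, v in itertools.pairwise(path))
            best = min(best, w)
    if include_connectors and np.isfinite(best):
        best += a.connector_length + b.connector_length
    return float(best)


def _add_min(g: nx.Graph, u, v, w: float) -> None:
    if u == v:
        return
    if g.has_edge(u, v):
        g[u][v]["weight"] = min(g[u][v]["weight"], w)
    else:
        g.add_edge(u, v, weight=w)


def random_small_network(rng: np.random.Generator, n_nodes: int) -> RoadNetwork:
    """Random planar-coordinate graph with <= 12 nodes; may be disconnected."""
    pts = rng.uniform(0, 1000, size=(n_nodes, 2))
    nodes = {i: tuple(pts[i]) for i in range(n_nodes)}
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.uniform() < 0.3:
                # stretch factor keeps lengths >= straight-line distance
                d = float(np.hypot(*(pts[i] - pts[j])))
                edges.append((i, j, d * float(rng.uniform(1.0, 1.5))))
    if not edges:
        edges.append((0, 1, float(np.hypot(*(pts[0] - pts[1]))) + 1.0))
    return RoadNetwork(nodes, edges)
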