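"""Pedestrian road network: graph container, point snapping, shortest-path
network distances and threshold catchments.

Distances are planar meters throughout.  Off-network points are attached to
the graph by perpendicular projection onto the nearest edge; the straight-line
connector from the original point to its projection can be included in or
excluded from every network distance (``include_connectors``).  Unreachable
pairs are reported as ``+inf``, never as a large finite placeholder, so that
downstream distance-decay weights cannot be silently corrupted.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TravelScope",
    "DEFAULT_SCOPES",
    "NetworkLocation",
    "RoadNetwork",
    "snap",
    "network_distance",
    "distance_to_greenspace",
    "catchment",
    "location_distances",
    "distance_matrix",
]


@dataclass(frozen=True)
class TravelScope:
    """A walking life-circle: a label and its network-distance threshold.

    The walking speed is carried as metadata only; the thresholds themselves
    (500/1000/2000 m for the 5/15/30-minute circles) are what the analysis
    uses.
    """

    label: str
    d0: float
    walking_speed_kmh: float = 5.0

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("travel scope threshold d0 must be positive")


#: The three walking life circles used by default.
DEFAULT_SCOPES: tuple[TravelScope, ...] = (
    TravelScope("5-min", 500.0),
    TravelScope("15-min", 1000.0),
    TravelScope("30-min", 2000.0),
)


@dataclass(frozen=True)
class NetworkLocation:
    """A point attached to the network: an edge, an offset along it, and the
    straight-line connector length from the original off-network point."""

    edge_id: int
    u: object
    v: object
    offset: float  # meters from node u along the edge
    connector_length: float
    point: tuple[float, float]
    snapped: tuple[float, float]


class RoadNetwork:
    """Undirected weighted pedestrian graph with planar node coordinates.

    Edges carry positive lengths (meters) that must be at least the
    straight-line distance between their endpoints.  Self-loops are rejected;
    parallel edges are simplified by keeping the shorter.
    """

    def __init__(
        self,
        nodes: Mapping[object, tuple[float, float]],
        edges: Iterable[tuple],
    ) -> None:
        self.graph = nx.Graph()
        for nid, (x, y) in nodes.items():
            self.graph.add_node(nid, pos=(float(x), float(y)))
        best: dict[tuple, float] = {}
        order: list[tuple] = []
        for e in edges:
            if len(e) == 2:
                u, v = e
                length = None
            else:
                u, v, length = e
            if u == v:
                raise ValueError(f"self-loop at node {u!r} is not allowed")
            if u not in self.graph or v not in self.graph:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            d = math.dist(self.graph.nodes[u]["pos"], self.graph.nodes[v]["pos"])
            if length is None:
                length = d
            length = float(length)
            if length <= 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has non-positive length")
            if length < d - 1e-6:
                raise ValueError(
                    f"edge ({u!r}, {v!r}) length {length} shorter than "
                    f"straight-line distance {d}"
                )
            key = (u, v) if repr(u) <= repr(v) else (v, u)
            if key in best:
                best[key] = min(best[key], length)  # parallel edge: keep shorter
            else:
                best[key] = length
                order.append(key)
        self.edges: list[tuple[object, object, float]] = []
        for eid, (u, v) in enumerate(order):
            length = best[(u, v)]
            self.graph.add_edge(u, v, length=length, eid=eid)
            self.edges.append((u, v, length))
        self._geom_cache: dict | None = None
        self._adj_cache: tuple | None = None

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def node_pos(self, nid) -> tuple[float, float]:
        return self.graph.nodes[nid]["pos"]

    # -- snapping geometry ---------------------------------------------
    def _geometry(self) -> dict:
        if self._geom_cache is None:
            ax, ay, bx, by, ln = [], [], [], [], []
            for u, v, length in self.edges:
                (x1, y1), (x2, y2) = self.node_pos(u), self.node_pos(v)
                ax.append(x1)
                ay.append(y1)
                bx.append(x2)
                by.append(y2)
                ln.append(length)
            self._geom_cache = {
                "ax": np.array(ax),
                "ay": np.array(ay),
                "bx": np.array(bx),
                "by": np.array(by),
                "length": np.array(ln),
            }
        return self._geom_cache

    # -- adjacency for Dijkstra ----------------------------------------
    def _adjacency(self):
        if self._adj_cache is None:
            index = {nid: i for i, nid in enumerate(self.graph.nodes)}
            adj: list[list[tuple[int, float]]] = [[] for _ in index]
            for u, v, data in self.graph.edges(data=True):
                iu, iv, w = index[u], index[v], data["length"]
                adj[iu].append((iv, w))
                adj[iv].append((iu, w))
            self._adj_cache = (index, adj)
        return self._adj_cache

    def node_distances(
        self, seeds: Sequence[tuple[object, float]], cutoff: float | None = None
    ) -> np.ndarray:
        """Dijkstra from virtual seeds ``(node, initial_distance)``.

        Returns an array of distances indexed like ``self._adjacency()``;
        unreached nodes are ``+inf``.
        """
        index, adj = self._adjacency()
        dist = np.full(len(index), np.inf)
        heap: list[tuple[float, int]] = []
        for node, d0 in seeds:
            i = index[node]
            if d0 < dist[i]:
                dist[i] = d0
                heapq.heappush(heap, (d0, i))
        while heap:
            d, i = heapq.heappop(heap)
            if d > dist[i]:
                continue
            if cutoff is not None and d > cutoff:
                continue
            for j, w in adj[i]:
                nd = d + w
                if nd < dist[j]:
                    dist[j] = nd
                    heapq.heappush(heap, (nd, j))
        return dist


# ----------------------------------------------------------------------
# Snapping
# ----------------------------------------------------------------------

def snap(point: tuple[float, float], network: RoadNetwork) -> NetworkLocation:
    """Project ``point`` onto the nearest edge of the network.

    The projection is perpendicular, clamped to the segment.  Ties between
    edges are broken deterministically toward the smallest edge id.
    """
    if network.n_edges == 0:
        raise ValueError("cannot snap to an empty network")
    g = network._geometry()
    px, py = float(point[0]), float(point[1])
    dx, dy = g["bx"] - g["ax"], g["by"] - g["ay"]
    seg2 = dx * dx + dy * dy
    t = ((px - g["ax"]) * dx + (py - g["ay"]) * dy) / np.where(seg2 > 0, seg2, 1.0)
    t = np.clip(t, 0.0, 1.0)
    cx, cy = g["ax"] + t * dx, g["ay"] + t * dy
    d2 = (px - cx) ** 2 + (py - cy) ** 2
    eid = int(np.argmin(d2))  # first minimum = smallest edge id
    u, v, length = network.edges[eid]
    return NetworkLocation(
        edge_id=eid,
        u=u,
        v=v,
        offset=float(t[eid] * length),
        connector_length=float(math.sqrt(d2[eid])),
        point=(px, py),
        snapped=(float(cx[eid]), float(cy[eid])),
    )


# ----------------------------------------------------------------------
# Distances
# ----------------------------------------------------------------------

def location_distances(
    sources: Sequence[NetworkLocation],
    targets: Sequence[NetworkLocation],
    network: RoadNetwork,
    include_connectors: bool = True,
    cutoff: float | None = None,
) -> np.ndarray:
    """Shortest network distance from the nearest of ``sources`` to every
    target location.

    Runs one multi-source Dijkstra, then evaluates each target from its
    edge's endpoints; pairs sharing an edge are additionally checked along
    the edge itself (the within-edge path does not pass through a node).
    """
    if not sources:
        raise ValueError("at least one source location is required")
    seeds = []
    by_edge: dict[int, list[tuple[float, float]]] = {}
    for s in sources:
        length = network.edges[s.edge_id][2]
        base = s.connector_length if include_connectors else 0.0
        seeds.append((s.u, base + s.offset))
        seeds.append((s.v, base + (length - s.offset)))
        by_edge.setdefault(s.edge_id, []).append((s.offset, base))
    dist = network.node_distances(seeds, cutoff=cutoff)
    index, _ = network._adjacency()

    out = np.empty(len(targets))
    for k, t in enumerate(targets):
        length = network.edges[t.edge_id][2]
        d = min(dist[index[t.u]] + t.offset, dist[index[t.v]] + (length - t.offset))
        for s_off, s_base in by_edge.get(t.edge_id, ()):
            d = min(d, s_base + abs(s_off - t.offset))
        if include_connectors:
            d += t.connector_length
        out[k] = d
    return out


def network_distance(
    origin: NetworkLocation,
    dest: NetworkLocation,
    network: RoadNetwork,
    include_connectors: bool = True,
) -> float:
    """Shortest-path distance between two snapped locations (meters), through
    the graph plus both connectors; ``+inf`` when no path exists."""
    return float(
        location_distances([origin], [dest], network, include_connectors)[0]
    )


def distance_to_greenspace(
    demand: NetworkLocation,
    snapped_access: Sequence[NetworkLocation],
    network: RoadNetwork,
    include_connectors: bool = True,
) -> float:
    """Network distance from a demand point to the nearest entrance of a
    green space (minimum over its access points)."""
    if not snapped_access:
        raise ValueError("green space has no access points")
    return float(
        location_distances(list(snapped_access), [demand], network, include_connectors)[0]
    )


def catchment(
    origin: NetworkLocation,
    d0: float,
    targets: Sequence[NetworkLocation],
    network: RoadNetwork,
    include_connectors: bool = True,
) -> list[tuple[int, float]]:
    """Targets within network distance ``d0`` of ``origin``.

    Returns ``(target_index, distance)`` pairs, boundary included; the
    distances are the ones used by the accessibility model downstream.
    """
    if d0 <= 0:
        raise ValueError("catchment radius d0 must be positive")
    d = location_distances([origin], targets, network, include_connectors)
    return [(i, float(di)) for i, di in enumerate(d) if di <= d0]


# ----------------------------------------------------------------------
# Supply-demand distance matrix
# ----------------------------------------------------------------------

def distance_matrix(
    supply_points: Mapping[object, Sequence[tuple[float, float]]],
    demand_points: Mapping[object, tuple[float, float]],
    network: RoadNetwork,
    max_distance: float,
    include_connectors: bool = True,
) -> pd.DataFrame:
    """Nearest-entrance network distances between every supply unit and every
    demand point, keeping pairs within ``max_distance``.

    ``supply_points`` maps a supply id to its access-point coordinates (one
    multi-source search per supply unit covers the nearest-entrance rule).
    Returns a tidy frame with columns ``greenspace_id, residential_id,
    distance_m``.
    """
    demand_ids = list(demand_points)
    demand_locs = [snap(demand_points[i], network) for i in demand_ids]
    rows: list[tuple[object, object, float]] = []
    for sid, pts in supply_points.items():
        if not pts:
            raise ValueError(f"supply unit {sid!r} has no access points")
        srcs = [snap(p, network) for p in pts]
        d = location_distances(
            srcs, demand_locs, network, include_connectors, cutoff=max_distance
        )
        keep = np.nonzero(d <= max_distance)[0]
        rows.extend((sid, demand_ids[k], float(d[k])) for k in keep)
    return pd.DataFrame(rows, columns=["greenspace_id", "residential_id", "distance_m"])
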