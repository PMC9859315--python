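"""Seeded synthetic-city generator.

Emulates the spatial structure the accessibility analysis assumes: a
connected pedestrian road lattice, sub-district polygons partitioning the
extent, residential rectangles with area-weighted census populations, and
green spaces in two size classes (large ones with several boundary
entrances, small ones served through their centroid).  A ``clustering`` knob
concentrates green-space supply in one quadrant so that runs reproduce the
empirical regime of interest: many residential areas unserved at the 500 m
scope, strong inequality, coverage growing with the travel threshold.

Everything is driven by a single integer seed; a fixed scenario reproduces
byte-identical layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon, box

from . import geodata_io
from .geodata_io import GreenSpace, ResidentialArea, SubDistrict
from .road_network import RoadNetwork

__all__ = ["CityScenario", "DegenerateScenarioError", "generate_road_network",
           "generate_zones", "generate_city"]


class DegenerateScenarioError(ValueError):
    """Scenario parameters cannot produce a usable city."""


@dataclass(frozen=True)
class CityScenario:
    """Parameters of a synthetic study region.

    Defaults mirror the scale of a mid-size Chinese main urban area:
    ~100 km^2, 39 sub-districts, 2020 residential areas and 85 green spaces
    whose areas are drawn log-uniformly between 0.5 and 50 ha (median 5 ha,
    so the two size classes are roughly balanced).  The default population
    gives a per-capita green-space supply of about 7 m^2/person.
    """

    seed: int = 0
    extent: tuple[float, float] = (10_000.0, 10_000.0)
    grid_spacing: float = 250.0
    n_subdistricts: int = 39
    n_residential: int = 2020
    n_greenspaces: int = 85
    greenspace_area_range: tuple[float, float] = (5_000.0, 500_000.0)
    large_space_threshold: float = 50_000.0
    clustering: float = 0.8
    total_population: int = 1_300_000
    edge_removal_fraction: float = 0.1

    def __post_init__(self) -> None:
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValueError("extent must be strictly positive")
        if min(self.n_subdistricts, self.n_residential, self.n_greenspaces) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering must lie in [0, 1]")
        lo, hi = self.greenspace_area_range
        if not (0 < lo <= hi):
            raise ValueError("greenspace_area_range must satisfy 0 < min <= max")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if not 0.0 <= self.edge_removal_fraction < 1.0:
            raise ValueError("edge_removal_fraction must lie in [0, 1)")
        if self.total_population < 0:
            raise ValueError("total_population must be nonnegative")

    def rng(self, stream: int) -> np.random.Generator:
        # independent, reproducible stream per generation stage
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


_STREAM_ROADS, _STREAM_ZONES, _STREAM_RES, _STREAM_GREEN, _STREAM_POP = range(5)


# ----------------------------------------------------------------------
# Road network
# ----------------------------------------------------------------------

def generate_road_network(scenario: CityScenario) -> RoadNetwork:
    """Rectangular lattice over the extent, optionally thinned by random
    edge removals that preserve connectivity."""
    w, h = scenario.extent
    nx_pts = int(np.floor(w / scenario.grid_spacing)) + 1
    ny_pts = int(np.floor(h / scenario.grid_spacing)) + 1
    if nx_pts < 2 or ny_pts < 2:
        raise DegenerateScenarioError(
            "extent smaller than one road grid cell; decrease grid_spacing"
        )
    nodes = {}
    for j in range(ny_pts):
        for i in range(nx_pts):
            nodes[j * nx_pts + i] = (i * scenario.grid_spacing, j * scenario.grid_spacing)
    edges = []
    for j in range(ny_pts):
        for i in range(nx_pts):
            nid = j * nx_pts + i
            if i + 1 < nx_pts:
                edges.append((nid, nid + 1))
            if j + 1 < ny_pts:
                edges.append((nid, nid + nx_pts))
    net = RoadNetwork(nodes, edges)
    n_remove = int(scenario.edge_removal_fraction * len(edges))
    if n_remove:
        rng = scenario.rng(_STREAM_ROADS)
        order = rng.permutation(len(edges))
        import networkx as nxlib

        g = net.graph.copy()
        removed = 0
        for k in order:
            if removed >= n_remove:
                break
            u, v = edges[int(k)]
            g.remove_edge(u, v)
            # keep only removals that leave the lattice connected
            if nxlib.has_path(g, u, v):
                removed += 1
            else:
                g.add_edge(u, v)
        kept = [(u, v) for u, v in g.edges]
        net = RoadNetwork(nodes, kept)
    return net


# ----------------------------------------------------------------------
# Zones: sub-districts, residential areas, green spaces
# ----------------------------------------------------------------------

def _partition_extent(scenario: CityScenario, rng: np.random.Generator) -> list[tuple]:
    """Recursive binary split of the extent rectangle into n_subdistricts
    rectangles (largest piece split first, at a random 35-65% fraction)."""
    w, h = scenario.extent
    rects = [(0.0, 0.0, w, h)]
    while len(rects) < scenario.n_subdistricts:
        rects.sort(key=lambda r: -(r[2] - r[0]) * (r[3] - r[1]))
        x0, y0, x1, y1 = rects.pop(0)
        f = rng.uniform(0.35, 0.65)
        if (x1 - x0) >= (y1 - y0):
            xm = x0 + f * (x1 - x0)
            rects += [(x0, y0, xm, y1), (xm, y0, x1, y1)]
        else:
            ym = y0 + f * (y1 - y0)
            rects += [(x0, y0, x1, ym), (x0, ym, x1, y1)]
    rects.sort()
    return rects


def _integer_allocation(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of ``weights/sum*total`` to integers that
    sum exactly to ``total``."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def generate_zones(
    scenario: CityScenario, network: RoadNetwork
) -> tuple[list[SubDistrict], list[ResidentialArea], list[GreenSpace]]:
    """Sub-districts partitioning the extent, residential rectangles inside
    them (populations by area weighting of a Dirichlet census split), and
    green spaces placed with the scenario's quadrant clustering."""
    if scenario.n_residential < scenario.n_subdistricts:
        raise ValueError(
            "need at least one residential area per sub-district: "
            f"{scenario.n_residential} < {scenario.n_subdistricts}"
        )
    w, h = scenario.extent
    rng_zone = scenario.rng(_STREAM_ZONES)
    rects = _partition_extent(scenario, rng_zone)

    # census totals per sub-district: Dirichlet split, integerized
    rng_pop = scenario.rng(_STREAM_POP)
    shares = rng_pop.dirichlet(np.full(scenario.n_subdistricts, 2.0))
    sd_pop = _integer_allocation(shares, scenario.total_population)
    subdistricts = [
        SubDistrict(
            id=f"S{k:03d}", name=f"Subdistrict {k:03d}",
            polygon=box(*rects[k]), population=int(sd_pop[k]),
        )
        for k in range(scenario.n_subdistricts)
    ]

    # residential rectangles: counts proportional to sub-district area, >= 1
    rng_res = scenario.rng(_STREAM_RES)
    areas = np.array([(r[2] - r[0]) * (r[3] - r[1]) for r in rects])
    counts = _integer_allocation(areas, scenario.n_residential - scenario.n_subdistricts) + 1
    residential: list[ResidentialArea] = []
    rid = 0
    for k, (x0, y0, x1, y1) in enumerate(rects):
        for _ in range(int(counts[k])):
            rw = min(rng_res.uniform(40.0, 160.0), (x1 - x0) * 0.9)
            rh = min(rng_res.uniform(40.0, 160.0), (y1 - y0) * 0.9)
            cx = rng_res.uniform(x0 + rw / 2, x1 - rw / 2)
            cy = rng_res.uniform(y0 + rh / 2, y1 - rh / 2)
            residential.append(
                ResidentialArea(
                    id=f"R{rid:04d}", subdistrict_id=subdistricts[k].id,
                    polygon=box(cx - rw / 2, cy - rh / 2, cx + rw / 2, cy + rh / 2),
                )
            )
            rid += 1
    residential, _ = geodata_io.disaggregate_population(subdistricts, residential)

    # green spaces: log-uniform areas, quadrant-clustered centers
    rng_g = scenario.rng(_STREAM_GREEN)
    lo, hi = scenario.greenspace_area_range
    gs_areas = np.exp(rng_g.uniform(np.log(lo), np.log(hi), scenario.n_greenspaces))
    quad = int(rng_g.integers(4))  # the focus quadrant for clustered supply
    qx0 = (quad % 2) * w / 2
    qy0 = (quad // 2) * h / 2
    greenspaces: list[GreenSpace] = []
    for g, area in enumerate(gs_areas):
        aspect = rng_g.uniform(0.6, 1.6)
        gw = min(np.sqrt(area * aspect), w * 0.95)
        gh = min(area / gw, h * 0.95)
        if rng_g.uniform() < scenario.clustering:
            cx = rng_g.uniform(qx0, qx0 + w / 2)
            cy = rng_g.uniform(qy0, qy0 + h / 2)
        else:
            cx = rng_g.uniform(0, w)
            cy = rng_g.uniform(0, h)
        cx = float(np.clip(cx, gw / 2, w - gw / 2))
        cy = float(np.clip(cy, gh / 2, h - gh / 2))
        poly = box(cx - gw / 2, cy - gh / 2, cx + gw / 2, cy + gh / 2)
        if poly.area >= scenario.large_space_threshold:
            n_ap = int(rng_g.integers(2, 5))
            fracs = np.sort(rng_g.uniform(0, 1, n_ap))
            ring = poly.exterior
            access = [ring.interpolate(f, normalized=True) for f in fracs]
        else:
            access = [poly.centroid]
        greenspaces.append(GreenSpace(id=f"G{g:03d}", polygon=poly, access_points=access))
    return subdistricts, residential, greenspaces


def generate_city(scenario: CityScenario):
    """Convenience wrapper: road network plus all zone layers."""
    network = generate_road_network(scenario)
    subdistricts, residential, greenspaces = generate_zones(scenario, network)
    return subdistricts, residential, greenspaces, network
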