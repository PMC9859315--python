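"""Spatial layers of the analysis (sub-districts, residential areas, green
spaces, roads): domain types, GeoJSON/CSV round-trip, validation, and
area-weighted population disaggregation.

All layers live in a common projected planar CRS with meter units.  The
pipeline never reprojects: files written here declare ``"crs_units": "m"`` at
the FeatureCollection level, and the reader rejects layers whose coordinates
look like geographic degrees unless that declaration is present.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape

from .road_network import RoadNetwork

__all__ = [
    "LARGE_SPACE_THRESHOLD",
    "SubDistrict",
    "ResidentialArea",
    "GreenSpace",
    "UnitError",
    "GeometryValidationError",
    "ReferentialIntegrityError",
    "demand_point_of",
    "load_layers",
    "write_layers",
    "disaggregate_population",
    "validate_population_estimate",
]

#: Green spaces at or above 5 ha are "large": they expose real entrances
#: rather than a single centroid access point.
LARGE_SPACE_THRESHOLD = 50_000.0  # m^2


class UnitError(ValueError):
    """Coordinates appear to be geographic degrees, not projected meters."""


class GeometryValidationError(ValueError):
    """A feature's geometry is invalid (e.g. self-intersecting)."""


class ReferentialIntegrityError(ValueError):
    """A residential area references a sub-district that does not exist."""


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------

@dataclass
class SubDistrict:
    """Census aggregation unit: polygon plus total population SP."""

    id: str
    name: str
    polygon: Polygon
    population: int

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"sub-district {self.id}: negative population")
        _check_geometry(self.id, self.polygon)


@dataclass
class ResidentialArea:
    """Demand unit: polygon, disaggregated population D_k and demand point."""

    id: str
    subdistrict_id: str
    polygon: Polygon
    population: float | None = None
    demand_point: Point = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_geometry(self.id, self.polygon)
        if self.polygon.area <= 0:
            raise ValueError(f"residential area {self.id}: zero area")
        if self.population is not None and self.population < 0:
            raise ValueError(f"residential area {self.id}: negative population")
        if self.demand_point is None:
            self.demand_point = demand_point_of(self.polygon)

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class GreenSpace:
    """Supply unit: polygon area S_j plus one or more access points.

    Small spaces (< 5 ha) carry exactly one access point at the centroid;
    large ones carry their surveyed entrances on the boundary.
    """

    id: str
    polygon: Polygon
    access_points: list[Point] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_geometry(self.id, self.polygon)
        if self.polygon.area <= 0:
            raise ValueError(f"green space {self.id}: zero area")
        if not self.access_points:
            if self.size_class == "small":
                self.access_points = [demand_point_of(self.polygon)]
            else:
                raise ValueError(f"green space {self.id}: no access points")

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def size_class(self) -> str:
        return "large" if self.polygon.area >= LARGE_SPACE_THRESHOLD else "small"


def demand_point_of(polygon: Polygon) -> Point:
    """Geometric center, with an interior representative point as fallback
    when the centroid of a non-convex polygon falls outside it."""
    c = polygon.centroid
    if polygon.covers(c):
        return c
    return polygon.representative_point()


def _check_geometry(fid: str, geom) -> None:
    if geom is None or geom.is_empty:
        raise GeometryValidationError(f"feature {fid}: empty geometry")
    if not geom.is_valid:
        raise GeometryValidationError(f"feature {fid}: invalid geometry")


# ----------------------------------------------------------------------
# GeoJSON / CSV round-trip
# ----------------------------------------------------------------------

def _degreeish(coords_bounds: tuple[float, float, float, float]) -> bool:
    minx, miny, maxx, maxy = coords_bounds
    return -180.0 <= minx <= maxx <= 180.0 and -90.0 <= miny <= maxy <= 90.0


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "crs_units": "m", "features": features}


def _read_collection(path: Path) -> dict:
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    return fc


def _check_units(fc: dict, geoms, path: Path) -> None:
    if fc.get("crs_units") == "m":
        return
    bounds = None
    for g in geoms:
        b = g.bounds
        bounds = b if bounds is None else (
            min(bounds[0], b[0]), min(bounds[1], b[1]),
            max(bounds[2], b[2]), max(bounds[3], b[3]),
        )
    if bounds is not None and _degreeish(bounds):
        raise UnitError(
            f"{path}: coordinates fit geographic degree ranges and no "
            "'crs_units: m' declaration is present; a projected CRS in "
            "meters is required"
        )


def write_layers(
    directory: str | Path,
    subdistricts: Sequence[SubDistrict],
    residential: Sequence[ResidentialArea],
    greenspaces: Sequence[GreenSpace],
    network: RoadNetwork,
) -> dict[str, Path]:
    """Write the four layers as GeoJSON plus the sub-district population CSV.

    Returns the paths written, keyed by layer name.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "subdistricts": directory / "subdistricts.geojson",
        "residential": directory / "residential.geojson",
        "greenspaces": directory / "greenspaces.geojson",
        "network": directory / "network.geojson",
        "population": directory / "subdistrict_population.csv",
    }

    sd_feats = [
        {
            "type": "Feature",
            "geometry": mapping(s.polygon),
            "properties": {"id": s.id, "name": s.name, "population": int(s.population)},
        }
        for s in subdistricts
    ]
    res_feats = [
        {
            "type": "Feature",
            "geometry": mapping(r.polygon),
            "properties": {
                "id": r.id,
                "subdistrict_id": r.subdistrict_id,
                "population": r.population,
            },
        }
        for r in residential
    ]
    gs_feats = [
        {
            "type": "Feature",
            "geometry": mapping(g.polygon),
            "properties": {
                "id": g.id,
                "access_points": [[p.x, p.y] for p in g.access_points],
            },
        }
        for g in greenspaces
    ]
    net_feats = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [list(network.node_pos(u)), list(network.node_pos(v))],
            },
            "properties": {"u": u, "v": v, "length_m": length},
        }
        for u, v, length in network.edges
    ]
    for key, feats in [
        ("subdistricts", sd_feats),
        ("residential", res_feats),
        ("greenspaces", gs_feats),
        ("network", net_feats),
    ]:
        with open(paths[key], "w") as fh:
            json.dump(_feature_collection(feats), fh)
    pd.DataFrame(
        [(s.id, s.name, int(s.population)) for s in subdistricts],
        columns=["id", "name", "population"],
    ).to_csv(paths["population"], index=False)
    return paths


def load_layers(
    directory: str | Path,
    population_csv: str | Path | None = None,
) -> tuple[list[SubDistrict], list[ResidentialArea], list[GreenSpace], RoadNetwork]:
    """Read and validate the four layers written by :func:`write_layers`.

    Sub-district populations come from the embedded ``population`` attribute
    or, when ``population_csv`` is given, from a CSV with columns
    ``id,name,population`` overriding the attributes.
    """
    directory = Path(directory)
    pops: dict[str, int] | None = None
    names: dict[str, str] = {}
    if population_csv is not None:
        tbl = pd.read_csv(population_csv, dtype={"id": str})
        pops = dict(zip(tbl["id"], tbl["population"].astype(int)))
        if "name" in tbl:
            names = dict(zip(tbl["id"], tbl["name"].astype(str)))

    fc = _read_collection(directory / "subdistricts.geojson")
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    _check_units(fc, geoms, directory / "subdistricts.geojson")
    subdistricts = []
    for f, g in zip(fc["features"], geoms):
        p = f["properties"]
        sid = str(p["id"])
        pop = pops[sid] if pops is not None else int(p["population"])
        subdistricts.append(
            SubDistrict(sid, names.get(sid, str(p.get("name", sid))), g, pop)
        )
    sd_ids = {s.id for s in subdistricts}

    fc = _read_collection(directory / "residential.geojson")
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    _check_units(fc, geoms, directory / "residential.geojson")
    residential = []
    for f, g in zip(fc["features"], geoms):
        p = f["properties"]
        rid, sid = str(p["id"]), str(p["subdistrict_id"])
        if sid not in sd_ids:
            raise ReferentialIntegrityError(
                f"residential area {rid} references unknown sub-district {sid}"
            )
        residential.append(ResidentialArea(rid, sid, g, p.get("population")))

    fc = _read_collection(directory / "greenspaces.geojson")
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    _check_units(fc, geoms, directory / "greenspaces.geojson")
    greenspaces = [
        GreenSpace(
            str(f["properties"]["id"]),
            g,
            [Point(x, y) for x, y in f["properties"].get("access_points", [])],
        )
        for f, g in zip(fc["features"], geoms)
    ]

    fc = _read_collection(directory / "network.geojson")
    nodes: dict[object, tuple[float, float]] = {}
    edges = []
    for f in fc["features"]:
        coords = f["geometry"]["coordinates"]
        p = f.get("properties") or {}
        u = p.get("u", tuple(coords[0]))
        v = p.get("v", tuple(coords[-1]))
        u = tuple(u) if isinstance(u, list) else u
        v = tuple(v) if isinstance(v, list) else v
        nodes[u] = tuple(coords[0])
        nodes[v] = tuple(coords[-1])
        edges.append((u, v, p.get("length_m")))
    network = RoadNetwork(nodes, edges)
    return subdistricts, residential, greenspaces, network


# ----------------------------------------------------------------------
# Population disaggregation (dasymetric areal weighting)
# ----------------------------------------------------------------------

def disaggregate_population(
    subdistricts: Sequence[SubDistrict],
    residential: Sequence[ResidentialArea],
) -> tuple[list[ResidentialArea], dict[str, int]]:
    """Spread each sub-district's census population over its residential
    areas proportionally to polygon area: D_k = RA_k / RA * SP.

    Populations are kept as reals (no rounding); rounding is a reporting
    concern.  Returns the updated residential list and a map of sub-district
    id -> population that could not be assigned because the sub-district
    contains no residential area (also raised as a warning, never dropped
    silently).
    """
    by_sd: dict[str, list[ResidentialArea]] = {}
    for r in residential:
        by_sd.setdefault(r.subdistrict_id, []).append(r)
    unassigned: dict[str, int] = {}
    out: list[ResidentialArea] = []
    for s in subdistricts:
        members = by_sd.pop(s.id, [])
        if not members:
            if s.population > 0:
                unassigned[s.id] = s.population
                warnings.warn(
                    f"sub-district {s.id} has population {s.population} but no "
                    "residential areas; population left unassigned",
                    stacklevel=2,
                )
            continue
        total_area = sum(m.area for m in members)
        for m in members:
            out.append(replace(m, population=m.area / total_area * s.population))
    if by_sd:
        raise ReferentialIntegrityError(
            f"residential areas reference unknown sub-districts: {sorted(by_sd)}"
        )
    return out, unassigned


def validate_population_estimate(
    residential: Sequence[ResidentialArea],
    household_counts: pd.DataFrame,
    persons_per_household: float = 3.5,
) -> pd.DataFrame:
    """Check disaggregated populations against surveyed household counts.

    For each sampled unit the accuracy is the symmetric ratio
    ``min(D_k, h*pph) / max(D_k, h*pph)`` (1 = perfect agreement); the frame
    carries a ``mean_accuracy`` attribute — the survey-wide average accuracy
    rate.
    """
    if household_counts.empty:
        raise ValueError("household validation table is empty")
    pops = {r.id: r.population for r in residential}
    unknown = set(household_counts["id"].astype(str)) - set(pops)
    if unknown:
        raise ReferentialIntegrityError(
            f"household table references unknown residential areas: {sorted(unknown)}"
        )
    rows = []
    for _, rec in household_counts.iterrows():
        rid = str(rec["id"])
        est = float(pops[rid] or 0.0)
        surveyed = float(rec["households"]) * persons_per_household
        if surveyed <= 0 or est <= 0:
            if surveyed <= 0:
                warnings.warn(
                    f"residential area {rid}: zero surveyed households", stacklevel=2
                )
            acc = 0.0
        else:
            acc = min(est, surveyed) / max(est, surveyed)
        rows.append((rid, est, surveyed, acc))
    report = pd.DataFrame(
        rows, columns=["id", "estimated", "surveyed", "accuracy"]
    )
    report.attrs["mean_accuracy"] = float(report["accuracy"].mean())
    return report
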