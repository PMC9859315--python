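import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon, box

from greenaccess.geodata_io import (
    GeometryValidationError,
    GreenSpace,
    ReferentialIntegrityError,
    ResidentialArea,
    SubDistrict,
    UnitError,
    demand_point_of,
    disaggregate_population,
    load_layers,
    validate_population_estimate,
    write_layers,
)


def make_city():
    sd = [
        SubDistrict("S0", "North", box(0, 0, 1000, 500), 3500),
        SubDistrict("S1", "South", box(0, 500, 1000, 1000), 1200),
    ]
    res = [
        ResidentialArea("R0", "S0", box(10, 10, 110, 110)),
        ResidentialArea("R1", "S0", box(300, 100, 400, 200)),
        ResidentialArea("R2", "S1", box(100, 600, 300, 800)),
    ]
    gs = [
        # 16 ha (large, two entrances) and 0.25 ha (small, centroid access)
        GreenSpace("G0", box(500, 500, 900, 900), [Point(500, 700), Point(900, 700)]),
        GreenSpace("G1", box(0, 0, 50, 50)),
    ]
    return sd, res, gs


class TestDomainTypes:
    def test_small_space_gets_centroid_access(self):
        g = GreenSpace("G", box(0, 0, 50, 50))
        assert g.size_class == "small"
        assert len(g.access_points) == 1
        assert g.access_points[0].equals(Point(25, 25))

    def test_large_space_requires_entrances(self):
        with pytest.raises(ValueError, match="access"):
            GreenSpace("G", box(0, 0, 400, 400))

    def test_demand_point_inside_non_convex(self):
        horseshoe = Polygon(
            [(0, 0), (10, 0), (10, 10), (7, 10), (7, 2), (3, 2), (3, 10), (0, 10)]
        )
        p = demand_point_of(horseshoe)
        assert horseshoe.covers(p)

    def test_invalid_geometry_names_offender(self):
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(GeometryValidationError, match="R7"):
            ResidentialArea("R7", "S0", bowtie)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, small_city):
        _, (sd, res, gs, net) = small_city
        write_layers(tmp_path, sd, res, gs, net)
        sd2, res2, gs2, net2 = load_layers(tmp_path)
        assert [s.id for s in sd2] == [s.id for s in sd]
        assert [s.population for s in sd2] == [s.population for s in sd]
        for a, b in zip(res, res2):
            assert a.subdistrict_id == b.subdistrict_id
            assert a.polygon.equals_exact(b.polygon, 1e-9)
            assert b.population == pytest.approx(a.population, abs=1e-9)
        for a, b in zip(gs, gs2):
            assert a.polygon.equals_exact(b.polygon, 1e-9)
            assert len(a.access_points) == len(b.access_points)
        assert net2.n_edges == net.n_edges
        assert sorted(l for _, _, l in net2.edges) == pytest.approx(
            sorted(l for _, _, l in net.edges)
        )

    def test_unknown_subdistrict_reference(self, tmp_path):
        sd, res, gs = make_city()
        res[1].subdistrict_id = "Z"
        from greenaccess.road_network import RoadNetwork

        net = RoadNetwork({0: (0, 0), 1: (1000, 0)}, [(0, 1)])
        write_layers(tmp_path, sd, res, gs, net)
        with pytest.raises(ReferentialIntegrityError, match="Z"):
            load_layers(tmp_path)

    def test_degree_coordinates_rejected(self, tmp_path, small_city):
        _, (sd, res, gs, net) = small_city
        write_layers(tmp_path, sd, res, gs, net)
        path = tmp_path / "subdistricts.geojson"
        fc = json.loads(path.read_text())
        del fc["crs_units"]
        for f in fc["features"]:  # shrink into degree ranges
            f["geometry"]["coordinates"] = [
                [[x / 1000.0, y / 1000.0] for x, y in ring]
                for ring in f["geometry"]["coordinates"]
            ]
        path.write_text(json.dumps(fc))
        with pytest.raises(UnitError, match="degree"):
            load_layers(tmp_path)

    def test_invalid_geometry_in_file(self, tmp_path):
        sd, res, gs = make_city()
        from greenaccess.road_network import RoadNetwork

        net = RoadNetwork({0: (0, 0), 1: (1000, 0)}, [(0, 1)])
        write_layers(tmp_path, sd, res, gs, net)
        path = tmp_path / "residential.geojson"
        fc = json.loads(path.read_text())
        fc["features"][0]["geometry"]["coordinates"] = [
            [[0, 0], [10, 10], [10, 0], [0, 10], [0, 0]]
        ]
        path.write_text(json.dumps(fc))
        with pytest.raises(GeometryValidationError, match="R0"):
            load_layers(tmp_path)


class TestDisaggregation:
    def test_single_unit_takes_all(self):
        sd = [SubDistrict("S0", "S0", box(0, 0, 100, 100), 3500)]
        res = [ResidentialArea("R0", "S0", box(0, 0, 10, 10))]
        out, unassigned = disaggregate_population(sd, res)
        assert out[0].population == pytest.approx(3500.0)
        assert unassigned == {}

    def test_equal_areas_split_evenly(self):
        sd = [SubDistrict("S0", "S0", box(0, 0, 100, 100), 3500)]
        res = [
            ResidentialArea("R0", "S0", box(0, 0, 10, 10)),
            ResidentialArea("R1", "S0", box(20, 20, 30, 30)),
        ]
        out, _ = disaggregate_population(sd, res)
        assert [r.population for r in out] == pytest.approx([1750.0, 1750.0])

    def test_area_weighting_hand_case(self):
        # 300 of 1000 m2 at SP = 3500 -> 1050
        sd = [SubDistrict("S0", "S0", box(0, 0, 100, 100), 3500)]
        res = [
            ResidentialArea("R0", "S0", box(0, 0, 30, 10)),
            ResidentialArea("R1", "S0", box(0, 20, 70, 30)),
        ]
        out, _ = disaggregate_population(sd, res)
        assert out[0].population == pytest.approx(1050.0)

    def test_orphan_population_warned_not_dropped(self):
        sd = [
            SubDistrict("S0", "S0", box(0, 0, 100, 100), 500),
            SubDistrict("S1", "S1", box(100, 0, 200, 100), 900),
        ]
        res = [ResidentialArea("R0", "S0", box(0, 0, 10, 10))]
        with pytest.warns(UserWarning, match="unassigned"):
            out, unassigned = disaggregate_population(sd, res)
        assert unassigned == {"S1": 900}
        total = sum(r.population for r in out) + sum(unassigned.values())
        assert total == pytest.approx(1400.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1.0, 1e4), min_size=1, max_size=6),
        st.integers(0, 10**6),
        st.floats(0.1, 100.0),
    )
    def test_conservation_and_scale_equivariance(self, areas, sp, c):
        sd = [SubDistrict("S0", "S0", box(0, 0, 1, 1), sp)]
        res = [
            ResidentialArea(f"R{i}", "S0", box(0, 0, a, 1.0))
            for i, a in enumerate(areas)
        ]
        out, _ = disaggregate_population(sd, res)
        assert sum(r.population for r in out) == pytest.approx(sp, rel=1e-9, abs=1e-6)
        sd_scaled = [SubDistrict("S0", "S0", box(0, 0, 1, 1), int(sp * 3))]
        out2, _ = disaggregate_population(sd_scaled, res)
        for a, b in zip(out, out2):
            assert b.population == pytest.approx(
                a.population * int(sp * 3) / sp if sp else 0.0, rel=1e-9, abs=1e-6
            )


class TestHouseholdValidation:
    def make_res(self, pops):
        return [
            ResidentialArea(f"R{i}", "S0", box(0, 0, 10, 10), population=p)
            for i, p in enumerate(pops)
        ]

    def test_perfect_agreement(self):
        res = self.make_res([35.0, 70.0])
        tbl = pd.DataFrame({"id": ["R0", "R1"], "households": [10, 20]})
        report = validate_population_estimate(res, tbl, 3.5)
        assert report.attrs["mean_accuracy"] == pytest.approx(1.0)

    def test_symmetric_ratio_hand_case(self):
        res = self.make_res([70.0])
        tbl = pd.DataFrame({"id": ["R0"], "households": [10]})
        report = validate_population_estimate(res, tbl, 3.5)
        assert report["accuracy"].iloc[0] == pytest.approx(0.5)

    def test_zero_households_warn_and_zero(self):
        res = self.make_res([70.0])
        tbl = pd.DataFrame({"id": ["R0"], "households": [0]})
        with pytest.warns(UserWarning, match="zero surveyed"):
            report = validate_population_estimate(res, tbl, 3.5)
        assert report["accuracy"].iloc[0] == 0.0

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            validate_population_estimate(
                self.make_res([1.0]), pd.DataFrame(columns=["id", "households"])
            )
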