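import itertools
import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from greenaccess.g2sfca import (
    GRADE_LABELS,
    INACCESSIBLE,
    gaussian_decay,
    grade_natural_breaks,
    natural_breaks,
    step1_ratios,
    step2_accessibility,
    conservation_residual,
)
from greenaccess.geodata_io import GreenSpace, ResidentialArea
from greenaccess.road_network import TravelScope

SCOPE = TravelScope("15-min", 1000.0)


def make_greenspace(gid: str, area: float) -> GreenSpace:
    side = math.sqrt(area)
    return GreenSpace(gid, box(0, 0, side, side))


def make_residential(rid: str, population: float) -> ResidentialArea:
    return ResidentialArea(rid, "S0", box(0, 0, 100, 100), population=population)


def dist_frame(rows):
    return pd.DataFrame(rows, columns=["greenspace_id", "residential_id", "distance_m"])


class TestGaussianDecay:
    def test_closed_form_endpoints(self):
        assert gaussian_decay(0.0, 500.0) == pytest.approx(1.0, abs=1e-15)
        assert gaussian_decay(500.0, 500.0) == pytest.approx(0.0, abs=1e-15)

    def test_half_distance_value(self):
        # (e^{-0.125} - e^{-0.5}) / (1 - e^{-0.5})
        assert gaussian_decay(500.0, 1000.0) == pytest.approx(0.70137, abs=1e-5)

    def test_strictly_decreasing(self):
        d = np.linspace(0.0, 1000.0, 1000)
        w = gaussian_decay(d, 1000.0)
        assert np.all(np.diff(w) < 0)
        assert np.all((w >= 0) & (w <= 1))

    def test_out_of_range_is_contract_violation(self):
        with pytest.raises(ValueError):
            gaussian_decay(1001.0, 1000.0)
        with pytest.raises(ValueError):
            gaussian_decay(-1.0, 1000.0)


class TestStep1:
    def test_single_resident_at_zero_distance(self):
        gs = [make_greenspace("G0", 1000.0)]
        res = [make_residential("R0", 100.0)]
        out = step1_ratios(gs, res, dist_frame([("G0", "R0", 0.0)]), SCOPE)
        assert out["R_j"].tolist() == pytest.approx([10.0])

    def test_demand_is_additive(self):
        gs = [make_greenspace("G0", 1000.0)]
        res = [make_residential("R0", 100.0), make_residential("R1", 100.0)]
        out = step1_ratios(
            gs, res, dist_frame([("G0", "R0", 0.0), ("G0", "R1", 0.0)]), SCOPE
        )
        assert out["R_j"].tolist() == pytest.approx([5.0])

    def test_half_distance_uses_decay_weight(self):
        gs = [make_greenspace("G0", 1000.0)]
        res = [make_residential("R0", 100.0)]
        out = step1_ratios(gs, res, dist_frame([("G0", "R0", 500.0)]), SCOPE)
        assert out["R_j"].tolist() == pytest.approx([1000.0 / (0.70137 * 100.0)], rel=1e-4)

    def test_empty_catchment_excluded(self):
        gs = [make_greenspace("G0", 1000.0), make_greenspace("G1", 500.0)]
        res = [make_residential("R0", 100.0)]
        out = step1_ratios(gs, res, dist_frame([("G0", "R0", 10.0)]), SCOPE)
        assert out["greenspace_id"].tolist() == ["G0"]


class TestStep2:
    def test_single_pair_conserves_supply_exactly(self):
        gs = [make_greenspace("G0", 12345.0)]
        res = [make_residential("R0", 77.0)]
        d = dist_frame([("G0", "R0", 640.0)])
        ratios = step1_ratios(gs, res, d, SCOPE)
        out = step2_accessibility(res, ratios, d, SCOPE)
        # decay cancels between the two steps: D_k * A_k = S_j
        assert 77.0 * out["A_k"].iloc[0] == pytest.approx(12345.0, rel=1e-12)

    def test_unit_with_no_supply_in_range_is_inaccessible(self):
        gs = [make_greenspace("G0", 1000.0)]
        res = [make_residential("R0", 10.0), make_residential("R1", 10.0)]
        d = dist_frame([("G0", "R0", 100.0), ("G0", "R1", 5000.0)])
        ratios = step1_ratios(gs, res, d, SCOPE)
        out = step2_accessibility(res, ratios, d, SCOPE).set_index("residential_id")
        assert out.loc["R1", "A_k"] == 0.0
        assert out.loc["R1", "grade"] == INACCESSIBLE
        assert not out.loc["R1", "accessible"]
        assert out.loc["R0", "accessible"]

    def test_matches_dense_matrix_oracle(self):
        rng = np.random.default_rng(12)
        n_g, n_r = 5, 9
        gs = [make_greenspace(f"G{j}", float(rng.uniform(500, 5000))) for j in range(n_g)]
        res = [make_residential(f"R{k}", float(rng.uniform(10, 500))) for k in range(n_r)]
        dmat = rng.uniform(0, 2000, size=(n_g, n_r))
        rows = [
            (f"G{j}", f"R{k}", dmat[j, k])
            for j in range(n_g)
            for k in range(n_r)
            if dmat[j, k] <= SCOPE.d0
        ]
        d = dist_frame(rows)
        ratios = step1_ratios(gs, res, d, SCOPE)
        out = step2_accessibility(res, ratios, d, SCOPE).set_index("residential_id")

        W = np.where(dmat <= SCOPE.d0, 1.0, np.nan)
        W = np.nan_to_num(W * gaussian_decay(np.clip(dmat, 0, SCOPE.d0), SCOPE.d0))
        D = np.array([r.population for r in res])
        S = np.array([g.area for g in gs])
        served = W @ D
        R = np.where(served > 0, S / np.where(served > 0, served, 1.0), 0.0)
        A = W.T @ R
        for k in range(n_r):
            assert out.loc[f"R{k}", "A_k"] == pytest.approx(A[k], rel=1e-12)
        # aggregate conservation against the served supply
        assert float(D @ A) == pytest.approx(float(S[served > 0].sum()), rel=1e-9)
        assert conservation_residual(res, out.reset_index(), ratios, gs) < 1e-9

    def test_scale_equivariance_in_supply(self):
        gs1 = [make_greenspace("G0", 2000.0), make_greenspace("G1", 700.0)]
        gs2 = [make_greenspace("G0", 6000.0), make_greenspace("G1", 2100.0)]
        res = [make_residential("R0", 50.0), make_residential("R1", 20.0)]
        d = dist_frame(
            [("G0", "R0", 100.0), ("G0", "R1", 900.0), ("G1", "R1", 400.0)]
        )
        a1 = step2_accessibility(res, step1_ratios(gs1, res, d, SCOPE), d, SCOPE)
        a2 = step2_accessibility(res, step1_ratios(gs2, res, d, SCOPE), d, SCOPE)
        assert a2["A_k"].to_numpy() == pytest.approx(3.0 * a1["A_k"].to_numpy())

    def test_zero_distances_reduce_to_classic_2sfca(self):
        gs = [make_greenspace("G0", 900.0), make_greenspace("G1", 400.0)]
        res = [make_residential("R0", 10.0), make_residential("R1", 30.0)]
        d = dist_frame(
            [(g.id, r.id, 0.0) for g in gs for r in res]
        )
        out = step2_accessibility(res, step1_ratios(gs, res, d, SCOPE), d, SCOPE)
        expected = (900.0 + 400.0) / 40.0  # pure supply over pooled demand
        assert out["A_k"].to_numpy() == pytest.approx([expected, expected])


class TestNaturalBreaks:
    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(2)
        centers = [0.0, 100.0, 200.0, 300.0, 400.0]
        values = np.concatenate(
            [c + rng.uniform(-5.0, 5.0, 8) for c in centers]
        )
        labels, breaks = natural_breaks(values, 5)
        for m, c in enumerate(centers):
            mask = np.abs(values - c) < 50.0
            assert set(labels[mask]) == {m}
        assert breaks == sorted(breaks)

    def test_cost_matches_exhaustive_partition_search(self):
        def sse(seg):
            seg = np.asarray(seg)
            return float(((seg - seg.mean()) ** 2).sum())

        rng = np.random.default_rng(8)
        for n in (6, 9, 12):
            v = np.sort(rng.uniform(0, 100, n))
            labels, _ = natural_breaks(v, 5)
            got = sum(sse(v[labels == m]) for m in range(5))
            best = min(
                sum(
                    sse(v[a:b])
                    for a, b in itertools.pairwise((0, *cuts, n))
                )
                for cuts in itertools.combinations(range(1, n), 4)
            )
            assert got == pytest.approx(best, abs=1e-9)

    def test_all_equal_values_error(self):
        with pytest.raises(ValueError, match="reduce"):
            natural_breaks([5.0] * 10, 5)

    def test_grade_labels_ascend_with_value(self):
        values = [2.0, 1.0, 102.0, 101.0, 202.0, 201.0, 302.0, 301.0, 402.0, 401.0]
        labels, _ = grade_natural_breaks(values, 5)
        by_value = [l for _, l in sorted(zip(values, labels))]
        assert by_value == [g for g in GRADE_LABELS for _ in range(2)]
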