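"""Equity and service-performance statistics over accessibility results.

Covers four instruments used to judge how fairly green-space service is
distributed across units (residential areas or sub-districts):

* Lorenz curve and Gini coefficient of per-capita accessibility, in the
  trapezoidal form G = 1 - (1/n)(2 * sum_{i<n} W_i + 1) over units sorted
  ascending (0 = perfect equity, upper bound (n-1)/n);
* location entropy AALQ_j = A_j / (S/P): a unit's accessibility relative to
  the study-wide per-capita supply, graded into fixed bins;
* effective service area/population ratios T_j, U_j per sub-district: the
  fraction of its residential area (population) covered by at least one
  green space within the travel threshold;
* grading-share tables: counts and percentages per accessibility or entropy
  grade, the accessible share, and the above-baseline share.

Percentages are reported to one decimal with half-up rounding.  In the
grade-share table the "accessible" summary row is the sum of the displayed
per-grade percentages, so the printed table stays internally additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .g2sfca import GRADE_LABELS, INACCESSIBLE
from .geodata_io import ResidentialArea, SubDistrict

__all__ = [
    "ENTROPY_BINS",
    "ENTROPY_LABELS",
    "LorenzGini",
    "percent",
    "lorenz_gini",
    "location_entropy",
    "service_coverage",
    "grading_shares",
    "shares_from_counts",
    "entropy_shares_from_counts",
    "area_class_shares",
]

#: Location-entropy grade bins: [0,0.5), [0.5,0.75), [0.75,1.2), [1.2,2.0), [2.0,inf)
ENTROPY_BINS = (0.0, 0.5, 0.75, 1.2, 2.0, np.inf)
ENTROPY_LABELS = ("Very low", "Lower", "Medium", "Higher", "Very high")


def percent(part, whole, decimals: int = 1) -> float:
    """Share of ``part`` in ``whole`` as a percentage rounded half-up."""
    if whole == 0:
        return 0.0
    q = Decimal(str(part)) / Decimal(str(whole)) * 100
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


# ----------------------------------------------------------------------
# Lorenz / Gini
# ----------------------------------------------------------------------

@dataclass
class LorenzGini:
    gini: float
    lorenz: list[tuple[float, float]]  # (cumulative unit fraction, cumulative share)
    n: int
    weighted: bool = False


def lorenz_gini(
    per_capita_values: Sequence[float],
    weights: Sequence[float] | None = None,
) -> LorenzGini:
    """Gini coefficient and Lorenz points of per-capita accessibility.

    Units enter unweighted by default (one observation each, sorted
    ascending); pass population ``weights`` for the population-weighted
    variant.  Values must be nonnegative and not all zero.
    """
    v = np.asarray(per_capita_values, dtype=float)
    if v.size < 2:
        raise ValueError("Gini requires at least two units")
    if np.any(v < 0):
        raise ValueError("per-capita values must be nonnegative")
    if v.sum() == 0:
        raise ValueError("Gini undefined when all values are zero")
    order = np.argsort(v, kind="stable")
    s = v[order]
    if weights is None:
        W = np.cumsum(s) / s.sum()
        n = s.size
        g = 1.0 - (2.0 * W[:-1].sum() + 1.0) / n
        points = [(0.0, 0.0)] + [(float((i + 1) / n), float(W[i])) for i in range(n)]
        return LorenzGini(gini=float(g), lorenz=points, n=n)
    p = np.asarray(weights, dtype=float)[order]
    if np.any(p < 0) or p.sum() == 0:
        raise ValueError("weights must be nonnegative with positive total")
    F = np.concatenate([[0.0], np.cumsum(p) / p.sum()])
    W = np.concatenate([[0.0], np.cumsum(p * s) / (p * s).sum()])
    g = 1.0 - float(np.sum(np.diff(F) * (W[1:] + W[:-1])))
    points = list(zip(F.tolist(), W.tolist()))
    return LorenzGini(gini=float(g), lorenz=points, n=s.size, weighted=True)


# ----------------------------------------------------------------------
# Location entropy
# ----------------------------------------------------------------------

def location_entropy(
    results: pd.DataFrame,
    total_supply: float,
    total_population: float,
    id_column: str = "residential_id",
) -> pd.DataFrame:
    """Location entropy AALQ per unit: accessibility over per-capita supply.

    ``results`` needs the unit id column and ``A_k``.  AALQ > 1 marks
    better-than-average service.
    """
    if total_supply <= 0 or total_population <= 0:
        raise ValueError("total supply and population must be positive")
    base = total_supply / total_population
    aalq = results["A_k"].to_numpy(dtype=float) / base
    idx = np.clip(np.searchsorted(ENTROPY_BINS, aalq, side="right") - 1, 0,
                  len(ENTROPY_LABELS) - 1)
    return pd.DataFrame(
        {
            "unit_id": results[id_column].to_numpy(),
            "AALQ": aalq,
            "grade": np.array(ENTROPY_LABELS, dtype=object)[idx],
            "above_average": aalq > 1.0,
        }
    )


# ----------------------------------------------------------------------
# Effective service coverage
# ----------------------------------------------------------------------

def service_coverage(
    subdistricts: Sequence[SubDistrict],
    residential: Sequence[ResidentialArea],
    covered: Mapping[str, bool],
) -> pd.DataFrame:
    """Effective service area ratio T_j and population ratio U_j per
    sub-district.

    ``covered`` flags residential areas with at least one green space within
    the scope.  T_j divides the covered residential area by the sub-district
    polygon area; U_j divides the covered population by the sub-district
    population (missing when that population is zero).
    """
    rows = []
    for s in subdistricts:
        members = [r for r in residential if r.subdistrict_id == s.id]
        cov = [r for r in members if covered.get(r.id, False)]
        t = sum(r.area for r in cov) / s.polygon.area
        pop = sum(float(r.population or 0.0) for r in members)
        u = (sum(float(r.population or 0.0) for r in cov) / pop) if pop > 0 else np.nan
        rows.append((s.id, t, u))
    return pd.DataFrame(rows, columns=["subdistrict_id", "T_j", "U_j"])


# ----------------------------------------------------------------------
# Grading-share tables
# ----------------------------------------------------------------------

def shares_from_counts(
    grade_counts: Mapping[str, int],
    total: int,
    above_baseline_count: int | None = None,
) -> pd.DataFrame:
    """Accessibility grade-share table from raw counts.

    Rows: the "Inaccessible" category, the five grades, an "Accessible"
    summary whose percentage is the sum of the displayed accessible-grade
    percentages (keeping the table additive at one decimal), and — when
    ``above_baseline_count`` is given — the share of accessible units whose
    score exceeds the study-wide per-capita baseline.  The direct half-up
    accessible percentage is also carried (``percent_direct``).
    """
    if total <= 0:
        raise ValueError("total unit count must be positive")
    rows = []
    acc_count = 0
    acc_pct_sum = 0.0
    for label in (INACCESSIBLE,) + tuple(GRADE_LABELS):
        c = int(grade_counts.get(label, 0))
        p = percent(c, total)
        rows.append((label, c, p, p))
        if label != INACCESSIBLE:
            acc_count += c
            acc_pct_sum += p
    rows.append(
        ("Accessible", acc_count, round(acc_pct_sum, 1), percent(acc_count, total))
    )
    if above_baseline_count is not None:
        rows.append(
            (
                "Above per-capita",
                int(above_baseline_count),
                percent(above_baseline_count, acc_count) if acc_count else 0.0,
                percent(above_baseline_count, acc_count) if acc_count else 0.0,
            )
        )
    return pd.DataFrame(rows, columns=["category", "count", "percent", "percent_direct"])


def entropy_shares_from_counts(
    grade_counts: Mapping[str, int], total: int
) -> pd.DataFrame:
    """Location-entropy grade shares plus the above-average and low-service
    (Very low + Lower) summary rows, percentages of all units."""
    if total <= 0:
        raise ValueError("total unit count must be positive")
    rows = [
        (label, int(grade_counts.get(label, 0)),
         percent(grade_counts.get(label, 0), total))
        for label in ENTROPY_LABELS
    ]
    low = int(grade_counts.get("Very low", 0)) + int(grade_counts.get("Lower", 0))
    rows.append(("Low service (Very low + Lower)", low, percent(low, total)))
    if "above_average" in grade_counts:
        ab = int(grade_counts["above_average"])
        rows.append(("Above average (AALQ > 1)", ab, percent(ab, total)))
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def area_class_shares(
    areas_m2: Sequence[float], threshold_m2: float = 50_000.0
) -> pd.DataFrame:
    """Two-class supply inventory (large vs small green spaces): counts and
    total areas with their percentage shares (two decimals, half-up)."""
    a = np.asarray(areas_m2, dtype=float)
    if a.size == 0:
        raise ValueError("no green-space areas given")
    large = a >= threshold_m2
    rows = []
    for label, mask in (("large", large), ("small", ~large)):
        rows.append(
            (
                label,
                int(mask.sum()),
                percent(int(mask.sum()), int(a.size), 2),
                float(a[mask].sum()),
                percent(float(a[mask].sum()), float(a.sum()), 2),
            )
        )
    return pd.DataFrame(
        rows, columns=["size_class", "count", "count_percent", "area_m2", "area_percent"]
    )


def grading_shares(
    accessibility: pd.DataFrame,
    entropy: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame | float]:
    """Summary statistics for one scope's graded results.

    Returns the accessibility grade-share table, the entropy share table
    (when entropy results are given) and the mean/standard deviation of A_k
    over accessible units.
    """
    counts = accessibility["grade"].value_counts().to_dict()
    above = None
    if "above_per_capita" in accessibility:
        above = int(
            (accessibility["above_per_capita"] & accessibility["accessible"]).sum()
        )
    out: dict[str, pd.DataFrame | float] = {
        "accessibility": shares_from_counts(counts, len(accessibility), above)
    }
    acc = accessibility.loc[accessibility["accessible"], "A_k"]
    out["mean_accessible"] = float(acc.mean()) if len(acc) else float("nan")
    out["std_accessible"] = float(acc.std(ddof=0)) if len(acc) else float("nan")
    if entropy is not None:
        ec = entropy["grade"].value_counts().to_dict()
        ec["above_average"] = int(entropy["above_average"].sum())
        out["entropy"] = entropy_shares_from_counts(ec, len(entropy))
    return out
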