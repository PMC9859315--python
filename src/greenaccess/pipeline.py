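"""End-to-end orchestration: simulate -> accessibility -> equity.

The library functions here do the work; the command-line front end in
``greenaccess.cli`` is a thin wrapper around them.  Every run writes a
machine-readable manifest (configuration, its hash, package versions) next
to its outputs, and all randomness flows from the single configuration seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, equity_metrics, g2sfca, geodata_io, road_network, synthetic_city
from .geodata_io import ResidentialArea
from .road_network import DEFAULT_SCOPES, TravelScope
from .synthetic_city import CityScenario

__all__ = ["PipelineConfig", "run_simulate", "run_accessibility", "run_equity",
           "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run.

    ``layers_dir`` defaults to ``<outdir>/layers``; when the layers are
    absent there, ``run_pipeline`` generates them from the scenario.  The
    per-capita baseline S/P is computed from the layers unless overridden.
    """

    outdir: Path = Path("runs/default")
    seed: int = 0
    layers_dir: Path | None = None
    scenario: CityScenario | None = None
    scopes: tuple[TravelScope, ...] = DEFAULT_SCOPES
    per_capita_baseline: float | None = None
    include_connectors: bool = True
    population_weighted_gini: bool = False
    subdistrict_entropy_mode: str = "aggregate"  # or "direct"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.layers_dir is None:
            self.layers_dir = self.outdir / "layers"
        self.layers_dir = Path(self.layers_dir)
        if not self.scopes:
            raise ValueError("at least one travel scope is required")
        if len({s.d0 for s in self.scopes}) != len(self.scopes):
            raise ValueError("travel scopes must have distinct thresholds")
        if self.per_capita_baseline is not None and self.per_capita_baseline <= 0:
            raise ValueError("per-capita baseline override must be positive")
        if self.subdistrict_entropy_mode not in ("aggregate", "direct"):
            raise ValueError("subdistrict_entropy_mode must be 'aggregate' or 'direct'")
        if self.scenario is None:
            self.scenario = CityScenario(seed=self.seed)

    # -- flat key-value serialisation ----------------------------------
    def to_flat_dict(self) -> dict:
        d = {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "layers_dir": str(self.layers_dir),
            "scope_d0s": [s.d0 for s in self.scopes],
            "scope_labels": [s.label for s in self.scopes],
            "per_capita_baseline": self.per_capita_baseline,
            "include_connectors": self.include_connectors,
            "population_weighted_gini": self.population_weighted_gini,
            "subdistrict_entropy_mode": self.subdistrict_entropy_mode,
        }
        for k, v in dataclasses.asdict(self.scenario).items():
            d[f"scenario_{k}"] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "PipelineConfig":
        sc_kwargs = {}
        for f in dataclasses.fields(CityScenario):
            key = f"scenario_{f.name}"
            if key in d:
                v = d[key]
                sc_kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        seed = int(d.get("seed", 0))
        sc_kwargs.setdefault("seed", seed)
        labels = d.get("scope_labels")
        d0s = d.get("scope_d0s")
        if d0s:
            labels = labels or [f"{int(x)}m" for x in d0s]
            scopes = tuple(TravelScope(l, float(x)) for l, x in zip(labels, d0s))
        else:
            scopes = DEFAULT_SCOPES
        return cls(
            outdir=Path(d.get("outdir", "runs/default")),
            seed=seed,
            layers_dir=Path(d["layers_dir"]) if d.get("layers_dir") else None,
            scenario=CityScenario(**sc_kwargs),
            scopes=scopes,
            per_capita_baseline=d.get("per_capita_baseline"),
            include_connectors=bool(d.get("include_connectors", True)),
            population_weighted_gini=bool(d.get("population_weighted_gini", False)),
            subdistrict_entropy_mode=d.get("subdistrict_entropy_mode", "aggregate"),
        )


def _write_manifest(config: PipelineConfig, stage: str) -> None:
    flat = config.to_flat_dict()
    payload = json.dumps(flat, sort_keys=True)
    manifest = {
        "stage": stage,
        "config": flat,
        "config_hash": hashlib.sha256(payload.encode()).hexdigest(),
        "versions": {
            "greenaccess": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    config.outdir.mkdir(parents=True, exist_ok=True)
    with open(config.outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ----------------------------------------------------------------------
# Stages
# ----------------------------------------------------------------------

def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate the synthetic city and write its layers + manifest."""
    sd, res, gs, net = synthetic_city.generate_city(config.scenario)
    paths = geodata_io.write_layers(config.layers_dir, sd, res, gs, net)
    _write_manifest(config, "simulate")
    logger.info(
        "simulated %d sub-districts, %d residential areas, %d green spaces, "
        "%d road edges", len(sd), len(res), len(gs), net.n_edges,
    )
    return paths


def _load(config: PipelineConfig):
    sd, res, gs, net = geodata_io.load_layers(config.layers_dir)
    if any(r.population is None for r in res):
        res, unassigned = geodata_io.disaggregate_population(sd, res)
        if unassigned:
            logger.warning("unassigned population: %s", unassigned)
    return sd, res, gs, net


def run_accessibility(config: PipelineConfig) -> dict:
    """G2SFCA accessibility per travel scope; writes one CSV per scope.

    Returns ``{"distances": ..., "baseline": S/P, "scopes": {label:
    {"ratios": ..., "results": ..., "breaks": ..., "residual": ...}}}``.
    """
    sd, res, gs, net = _load(config)
    total_supply = sum(g.area for g in gs)
    total_pop = sum(s.population for s in sd)
    baseline = config.per_capita_baseline
    if baseline is None:
        baseline = total_supply / total_pop if total_pop > 0 else float("inf")
    max_d0 = max(s.d0 for s in config.scopes)
    supply_pts = {g.id: [(p.x, p.y) for p in g.access_points] for g in gs}
    demand_pts = {r.id: (r.demand_point.x, r.demand_point.y) for r in res}
    if not gs:
        distances = pd.DataFrame(
            columns=["greenspace_id", "residential_id", "distance_m"]
        )
        logger.warning("no green spaces in the study area: all units inaccessible")
    else:
        distances = road_network.distance_matrix(
            supply_pts, demand_pts, net, max_d0, config.include_connectors
        )
    config.outdir.mkdir(parents=True, exist_ok=True)
    distances.to_csv(config.outdir / "distance_matrix.csv", index=False)

    out: dict = {"distances": distances, "baseline": baseline, "scopes": {}}
    for scope in config.scopes:
        ratios = g2sfca.step1_ratios(gs, res, distances, scope)
        results = g2sfca.step2_accessibility(res, ratios, distances, scope, baseline)
        residual = g2sfca.conservation_residual(res, results, ratios, gs)
        grades = results["grade"].value_counts().to_dict()
        logger.info(
            "%s: %d/%d accessible, conservation residual %.2e, grades %s",
            scope.label, int(results["accessible"].sum()), len(results),
            residual, grades,
        )
        pos = results.loc[results["accessible"] & (results["A_k"] > 0), "A_k"]
        breaks: list[float] = []
        if len(pos):
            n_classes = min(len(g2sfca.GRADE_LABELS), pos.nunique())
            _, breaks = g2sfca.natural_breaks(pos.to_numpy(), n_classes)
            logger.info("%s natural-break upper bounds: %s", scope.label, breaks)
        results.to_csv(
            config.outdir / f"accessibility_{scope.label}.csv", index=False
        )
        out["scopes"][scope.label] = {
            "ratios": ratios, "results": results,
            "breaks": breaks, "residual": residual,
        }
    _write_manifest(config, "accessibility")
    return out


def _subdistrict_scores(
    sd, res: Sequence[ResidentialArea], results: pd.DataFrame
) -> pd.DataFrame:
    """Population-weighted mean accessibility of member residential areas."""
    a = results.set_index("residential_id")["A_k"]
    rows = []
    for s in sd:
        members = [r for r in res if r.subdistrict_id == s.id]
        w = np.array([float(r.population or 0.0) for r in members])
        if len(members) == 0 or w.sum() == 0:
            rows.append((s.id, np.nan))
            continue
        v = np.array([a.get(r.id, 0.0) for r in members])
        rows.append((s.id, float(np.average(v, weights=w))))
    return pd.DataFrame(rows, columns=["subdistrict_id", "A_k"])


def run_equity(config: PipelineConfig, access: dict | None = None) -> dict:
    """Equity statistics per scope and unit level; writes CSVs and the
    Lorenz plot.  ``access`` is the dict from :func:`run_accessibility`;
    when omitted the accessibility CSVs written earlier are required."""
    sd, res, gs, net = _load(config)
    total_supply = sum(g.area for g in gs)
    total_pop = sum(s.population for s in sd)

    if access is None:
        access = {"scopes": {}}
        for scope in config.scopes:
            path = config.outdir / f"accessibility_{scope.label}.csv"
            if not path.exists():
                raise FileNotFoundError(
                    f"missing accessibility results {path}; run the "
                    "accessibility stage first"
                )
            access["scopes"][scope.label] = {"results": pd.read_csv(path)}

    gini_rows = []
    lorenz_rows = []
    summary: dict = {
        "per_capita_supply": (total_supply / total_pop) if total_pop else float("nan"),
        "scopes": {},
    }
    pops = np.array([float(r.population or 0.0) for r in res])
    for scope in config.scopes:
        results = access["scopes"][scope.label]["results"]
        results = results.set_index("residential_id").loc[[r.id for r in res]].reset_index()
        weights = pops if config.population_weighted_gini else None
        lg_res = equity_metrics.lorenz_gini(results["A_k"].to_numpy(), weights)
        sd_scores = _subdistrict_scores(sd, res, results)
        valid = sd_scores.dropna()
        lg_sd = equity_metrics.lorenz_gini(valid["A_k"].to_numpy())
        gini_rows.append((scope.label, "residential", lg_res.gini, lg_res.n))
        gini_rows.append((scope.label, "subdistrict", lg_sd.gini, lg_sd.n))
        for frac, share in lg_res.lorenz:
            lorenz_rows.append((scope.label, "residential", frac, share))
        for frac, share in lg_sd.lorenz:
            lorenz_rows.append((scope.label, "subdistrict", frac, share))

        entropy_res = equity_metrics.location_entropy(
            results, total_supply, total_pop
        )
        if config.subdistrict_entropy_mode == "direct":
            sd_results = _direct_subdistrict_accessibility(config, sd, gs, net, scope)
        else:
            sd_results = valid.rename(columns={"subdistrict_id": "residential_id"})
        entropy_sd = equity_metrics.location_entropy(
            sd_results, total_supply, total_pop
        )
        covered = dict(zip(results["residential_id"], results["accessible"]))
        coverage = equity_metrics.service_coverage(sd, res, covered)
        shares = equity_metrics.grading_shares(results, entropy_res)

        entropy_res.to_csv(config.outdir / f"entropy_{scope.label}.csv", index=False)
        entropy_sd.to_csv(
            config.outdir / f"entropy_subdistrict_{scope.label}.csv", index=False
        )
        coverage.to_csv(config.outdir / f"coverage_{scope.label}.csv", index=False)
        shares["accessibility"].to_csv(
            config.outdir / f"shares_{scope.label}.csv", index=False
        )
        shares["entropy"].to_csv(
            config.outdir / f"entropy_shares_{scope.label}.csv", index=False
        )

        acc_table = shares["accessibility"].set_index("category")
        summary["scopes"][scope.label] = {
            "d0": scope.d0,
            "accessible_count": int(acc_table.loc["Accessible", "count"]),
            "accessible_percent": float(acc_table.loc["Accessible", "percent"]),
            "accessible_percent_direct": float(
                acc_table.loc["Accessible", "percent_direct"]
            ),
            "gini_residential": lg_res.gini,
            "gini_subdistrict": lg_sd.gini,
            "mean_accessible": shares["mean_accessible"],
            "std_accessible": shares["std_accessible"],
            "above_average_entropy_count": int(entropy_res["above_average"].sum()),
            "above_average_entropy_percent": equity_metrics.percent(
                int(entropy_res["above_average"].sum()), len(entropy_res)
            ),
            "mean_U": float(coverage["U_j"].mean(skipna=True)),
            "mean_T": float(coverage["T_j"].mean(skipna=True)),
        }
        if "residual" in access["scopes"][scope.label]:
            summary["scopes"][scope.label]["conservation_residual"] = access[
                "scopes"
            ][scope.label]["residual"]

    pd.DataFrame(gini_rows, columns=["scope", "level", "gini", "n"]).to_csv(
        config.outdir / "gini_summary.csv", index=False
    )
    pd.DataFrame(
        lorenz_rows, columns=["scope", "level", "unit_fraction", "share"]
    ).to_csv(config.outdir / "lorenz_points.csv", index=False)
    _plot_lorenz(config, lorenz_rows)
    with open(config.outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_manifest(config, "equity")
    return summary


def _direct_subdistrict_accessibility(config, sd, gs, net, scope) -> pd.DataFrame:
    """Independent sub-district-level G2SFCA run: demand points are the
    sub-district representative points carrying the census population."""
    pseudo = [
        ResidentialArea(s.id, s.id, s.polygon, population=float(s.population))
        for s in sd
    ]
    supply_pts = {g.id: [(p.x, p.y) for p in g.access_points] for g in gs}
    demand_pts = {r.id: (r.demand_point.x, r.demand_point.y) for r in pseudo}
    if not gs:
        dist = pd.DataFrame(columns=["greenspace_id", "residential_id", "distance_m"])
    else:
        dist = road_network.distance_matrix(
            supply_pts, demand_pts, net, scope.d0, config.include_connectors
        )
    ratios = g2sfca.step1_ratios(gs, pseudo, dist, scope)
    return g2sfca.step2_accessibility(pseudo, ratios, dist, scope)


def _plot_lorenz(config: PipelineConfig, lorenz_rows) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame(
        lorenz_rows, columns=["scope", "level", "unit_fraction", "share"]
    )
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharey=True)
    for ax, level in zip(axes, ["residential", "subdistrict"]):
        for scope, grp in df[df["level"] == level].groupby("scope", sort=False):
            ax.plot(grp["unit_fraction"], grp["share"], label=scope)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="perfect equity")
        ax.set_title(f"{level} scale")
        ax.set_xlabel("cumulative share of units")
        ax.legend(fontsize=8)
    axes[0].set_ylabel("cumulative share of per-capita accessibility")
    fig.tight_layout()
    fig.savefig(config.outdir / "lorenz.png", dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate (when layers are absent) -> accessibility -> equity."""
    if not (Path(config.layers_dir) / "subdistricts.geojson").exists():
        run_simulate(config)
    access = run_accessibility(config)
    return run_equity(config, access)
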