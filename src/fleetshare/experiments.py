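"""Scenario library, sweep driver and figure-level analysis.

The scenario library ships two frozen exemplar parameterisations that sit at
contrasting corners of the model's ecological space: a ``whiting``-like
pelagic target (large, rich, mobile schools) and a ``groundfish``-like
demersal target (small, lean, sedentary schools).  Sweeps cross a scenario
with grids of the sharing level λ, school lifespan τ_l (inverse mobility),
allowed depletion fraction T/P and the management kind, running seeded
replicate seasons for every cell and collecting tidy long-format tables.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, replace, asdict, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agents import AgentParams
from .metrics import (
    catch_rate_series,
    cpue,
    fleet_rate_series,
    time_averaged_rates,
    objective_curves_from_summaries,
    optimal_lambda,
    divergence_index,
    ifq_tac_ratio,
)
from .season import ManagementPolicy, SeasonConfig, derive_seeds, run_season
from .world import WorldConfig

__all__ = [
    "Scenario",
    "SweepGrid",
    "SweepTable",
    "build_scenario",
    "list_scenarios",
    "run_sweep",
    "analyze_sweep",
]

_SCENARIO_PKG = "fleetshare.scenarios"


@dataclass(frozen=True)
class Scenario:
    """A frozen, content-hashed parameterisation of fleet and landscape."""

    name: str
    world: WorldConfig
    agents: AgentParams
    n_agents: int
    T: float  # default total allowable catch
    t_max: float  # default hard time cap
    notes: str = ""
    provenance: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "world": asdict(self.world),
            "agents": asdict(self.agents),
            "n_agents": self.n_agents,
            "management_defaults": {"T": self.T, "t_max": self.t_max},
            "notes": self.notes,
            "provenance": self.provenance,
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return f"{zlib.crc32(blob):08x}"

    @classmethod
    def from_dict(cls, data: Mapping) -> "Scenario":
        mgmt = data.get("management_defaults", {})
        return cls(
            name=str(data["name"]),
            world=WorldConfig(**data["world"]),
            agents=AgentParams(**data["agents"]),
            n_agents=int(data["n_agents"]),
            T=float(mgmt["T"]),
            t_max=float(mgmt["t_max"]),
            notes=str(data.get("notes", "")),
            provenance=str(data.get("provenance", "")),
        )

    def season_config(
        self,
        lam: float,
        management: str = "TAC",
        depletion: float = 0.0,
        tau_l: float | None = None,
        T: float | None = None,
    ) -> SeasonConfig:
        """Materialise a season config for one sweep cell."""
        world = self.world if tau_l is None else replace(self.world, tau_l=tau_l)
        T = self.T if T is None else T
        return SeasonConfig(
            world=world,
            agents=self.agents,
            n_agents=self.n_agents,
            lam=lam,
            management=ManagementPolicy(
                kind=management, T=T, n_agents=self.n_agents, t_max=self.t_max
            ),
            depletion=depletion,
        )


def list_scenarios() -> list[str]:
    """Names of the scenarios shipped with the package."""
    return sorted(
        p.name.removesuffix(".json")
        for p in resources.files(_SCENARIO_PKG).iterdir()
        if p.name.endswith(".json")
    )


def build_scenario(spec: str | Mapping) -> Scenario:
    """Load a named library scenario or build one from a complete mapping."""
    if isinstance(spec, Mapping):
        return Scenario.from_dict(spec)
    available = list_scenarios()
    if spec not in available:
        raise ValueError(
            f"unknown scenario {spec!r}; available scenarios: {', '.join(available)}"
        )
    data = json.loads(
        resources.files(_SCENARIO_PKG).joinpath(f"{spec}.json").read_text()
    )
    return Scenario.from_dict(data)


def default_lambda_grid() -> tuple[float, ...]:
    """The canonical sharing grid, λ = 0.0–1.0 in 11 steps."""
    return tuple(np.round(np.linspace(0.0, 1.0, 11), 10).tolist())


@dataclass(frozen=True)
class SweepGrid:
    """Experimental design crossed with a scenario by :func:`run_sweep`.

    ``tau_ls`` of ``None`` keeps the scenario's own lifespan (a pure λ
    sweep); otherwise supply log-spaced lifespans to scan species mobility.
    ``depletions`` are allowed depletion fractions T/P, with 0 meaning the
    renewable (non-depleting) baseline.
    """

    lams: tuple[float, ...] = field(default_factory=default_lambda_grid)
    tau_ls: tuple[float, ...] | None = None
    depletions: tuple[float, ...] = (0.0,)
    managements: tuple[str, ...] = ("TAC",)
    replicates: int = 30
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.lams:
            raise ValueError("grid.lams must be non-empty")
        if self.tau_ls is not None and not self.tau_ls:
            raise ValueError("grid.tau_ls must be non-empty or None")
        if not self.depletions:
            raise ValueError("grid.depletions must be non-empty")
        if not self.managements:
            raise ValueError("grid.managements must be non-empty")
        if self.replicates < 1:
            raise ValueError("grid.replicates must be >= 1")

    def cells(self, scenario: Scenario):
        tau_ls = self.tau_ls if self.tau_ls is not None else (scenario.world.tau_l,)
        return itertools.product(self.managements, tau_ls, self.depletions, self.lams)


@dataclass
class SweepTable:
    """Long-format sweep results.

    ``agents``: one row per (cell, replicate, agent) with CPUE, catch and
    effort.  ``seasons``: one row per (cell, replicate) with duration and the
    windowed summary statistics feeding the objective functions.
    """

    agents: pd.DataFrame
    seasons: pd.DataFrame
    scenario_hash: str
    grid: dict

    CELL_KEYS = ["management", "tau_l", "depletion", "lam"]

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.agents.to_csv(outdir / "agents.csv", index=False)
        self.seasons.to_csv(outdir / "seasons.csv", index=False)
        (outdir / "meta.json").write_text(
            json.dumps({"scenario_hash": self.scenario_hash, "grid": self.grid}, indent=2)
        )

    @classmethod
    def from_dir(cls, outdir: str | Path) -> "SweepTable":
        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        return cls(
            agents=pd.read_csv(outdir / "agents.csv"),
            seasons=pd.read_csv(outdir / "seasons.csv"),
            scenario_hash=meta["scenario_hash"],
            grid=meta["grid"],
        )


def _cell_key(scenario_hash: str, cell: tuple, master_seed: int) -> int:
    # replicate count is deliberately excluded: replicate seeds are a
    # prefix-stable stream, so growing a grid appends without reseeding
    blob = json.dumps(
        [scenario_hash, list(cell), master_seed], sort_keys=True
    ).encode()
    return zlib.crc32(blob)


def _season_summaries(result, scenario, cell, replicate, seed):
    management, tau_l, depletion, lam = cell
    per_agent, fleet_mean = cpue(result)
    series = catch_rate_series(result)
    a_i = time_averaged_rates(series)
    fleet_t = fleet_rate_series(series)
    base = {
        "scenario": scenario.name,
        "management": management,
        "tau_l": tau_l,
        "depletion": depletion,
        "lam": lam,
        "replicate": replicate,
        "seed": seed,
    }
    season_row = dict(
        base,
        duration=result.duration,
        total_catch=result.total_catch,
        mean_rate=float(np.nanmean(a_i)),
        between_agent_std=float(np.std(a_i, ddof=0)),
        temporal_std=float(np.nanstd(fleet_t, ddof=0)),
        terminated_by=result.terminated_by,
    )
    agent_rows = [
        dict(
            base,
            agent=i,
            cpue=float(per_agent[i]),
            catch=float(result.catch_totals[i]),
            active_time=float(result.active_times[i]),
            retirement_time=(
                None
                if np.isnan(result.retirement_times[i])
                else float(result.retirement_times[i])
            ),
        )
        for i in range(result.n_agents)
    ]
    return season_row, agent_rows


def run_sweep(
    grid: SweepGrid,
    scenario: Scenario,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> SweepTable:
    """Run every cell of the grid with seeded replicates.

    The table is a pure function of (scenario hash, grid, master seed):
    per-cell seeds are derived from the master seed and a stable hash of the
    cell coordinates, so adding replicates or grid values appends new records
    without changing existing ones.  With ``cache_dir`` set, completed cells
    are stored as CSV and skipped on re-runs.
    """
    scn_hash = scenario.content_hash()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    season_rows: list[dict] = []
    agent_rows: list[dict] = []
    cells = list(grid.cells(scenario))
    for cell in cells:
        management, tau_l, depletion, lam = cell
        key = _cell_key(scn_hash, cell, grid.master_seed)
        cache_file = (
            cache / f"cell_{key:08x}_r{grid.replicates}.json"
            if cache is not None
            else None
        )
        if cache_file is not None and cache_file.exists():
            blob = json.loads(cache_file.read_text())
            season_rows.extend(blob["seasons"])
            agent_rows.extend(blob["agents"])
            continue
        seeds = derive_seeds(grid.master_seed, grid.replicates, key=(key,))
        cfg = scenario.season_config(
            lam=lam, management=management, depletion=depletion, tau_l=tau_l
        )
        cell_seasons, cell_agents = [], []
        for rep, seed in enumerate(seeds):
            result = run_season(cfg, seed)
            srow, arows = _season_summaries(result, scenario, cell, rep, seed)
            cell_seasons.append(srow)
            cell_agents.extend(arows)
        if progress:
            print(f"cell {cell}: {grid.replicates} replicates done", flush=True)
        if cache_file is not None:
            cache_file.write_text(
                json.dumps({"seasons": cell_seasons, "agents": cell_agents})
            )
        season_rows.extend(cell_seasons)
        agent_rows.extend(cell_agents)
    return SweepTable(
        agents=pd.DataFrame(agent_rows),
        seasons=pd.DataFrame(season_rows),
        scenario_hash=scn_hash,
        grid={
            "lams": list(grid.lams),
            "tau_ls": None if grid.tau_ls is None else list(grid.tau_ls),
            "depletions": list(grid.depletions),
            "managements": list(grid.managements),
            "replicates": grid.replicates,
            "master_seed": grid.master_seed,
        },
    )


def _group_curves_frame(agents: pd.DataFrame, q: float) -> pd.DataFrame:
    """Replicate-averaged top/bottom/fleet CPUE per cell and λ."""
    rows = []
    group_cols = SweepTable.CELL_KEYS
    for cell_vals, cell_df in agents.groupby(group_cols, sort=True):
        tops, bottoms, fleets = [], [], []
        for _, rep_df in cell_df.groupby("replicate"):
            vals = rep_df.sort_values("agent")["cpue"].to_numpy()
            n = len(vals)
            k = max(int(np.ceil(q * n)), 1)
            ids = np.arange(n)
            order_up = np.lexsort((ids, vals))
            order_down = np.lexsort((ids, -vals))
            bottoms.append(vals[order_up[:k]].mean())
            tops.append(vals[order_down[:k]].mean())
            fleets.append(vals.mean())
        rows.append(
            dict(
                zip(group_cols, cell_vals),
                top_cpue=float(np.mean(tops)),
                bottom_cpue=float(np.mean(bottoms)),
                fleet_cpue=float(np.mean(fleets)),
            )
        )
    return pd.DataFrame(rows)


def analyze_sweep(table: SweepTable, q: float = 0.1) -> dict[str, pd.DataFrame]:
    """Reduce a sweep table to figure-level products.

    Returns data frames keyed by product name:

    - ``cpue_vs_lambda``: fleet mean CPUE and the 80% inter-agent interval
      per λ and cell;
    - ``group_curves``: replicate-averaged top/bottom/fleet CPUE per λ;
    - ``lambda_star``: CPUE-optimal λ for each group plus the divergence
      index 1 − (λ+/λ−) per (management, mobility, depletion) cell;
    - ``objectives``: O_CPUE / O_equity / O_stability per cell and λ;
    - ``ifq_tac`` (only when both managements are present): the group-level
      (H_IFQ/H_TAC) − 1 at each group's own optimal sharing level.
    """
    if table.agents.empty or table.seasons.empty:
        raise ValueError("analyze_sweep: empty sweep table")
    agents, seasons = table.agents, table.seasons

    # (a) fleet curve with 80% inter-agent interval
    cell_lam = SweepTable.CELL_KEYS
    cpue_rows = []
    for cell_vals, df in agents.groupby(cell_lam, sort=True):
        vals = df["cpue"].to_numpy()
        cpue_rows.append(
            dict(
                zip(cell_lam, cell_vals),
                fleet_cpue=float(np.mean(vals)),
                q10=float(np.quantile(vals, 0.1)),
                q90=float(np.quantile(vals, 0.9)),
            )
        )
    cpue_vs_lambda = pd.DataFrame(cpue_rows)

    # (b) group curves and per-cell optima
    group_curves = _group_curves_frame(agents, q)
    outer = ["management", "tau_l", "depletion"]
    star_rows = []
    for cell_vals, df in group_curves.groupby(outer, sort=True):
        top_curve = dict(zip(df["lam"], df["top_cpue"]))
        bottom_curve = dict(zip(df["lam"], df["bottom_cpue"]))
        lam_plus = optimal_lambda(top_curve)
        lam_minus = optimal_lambda(bottom_curve)
        star_rows.append(
            dict(
                zip(outer, cell_vals),
                lam_plus=lam_plus,
                lam_minus=lam_minus,
                divergence=divergence_index(lam_plus, lam_minus),
                top_cpue_at_opt=top_curve[lam_plus],
                bottom_cpue_at_opt=bottom_curve[lam_minus],
            )
        )
    lambda_star = pd.DataFrame(star_rows)

    # (c) objective surfaces
    obj_rows = []
    for cell_vals, df in seasons.groupby(outer, sort=True):
        agg = df.groupby("lam", sort=True)[
            ["mean_rate", "between_agent_std", "temporal_std"]
        ].mean()
        curves = objective_curves_from_summaries(
            agg.index.to_numpy(),
            agg["mean_rate"].to_numpy(),
            agg["between_agent_std"].to_numpy(),
            agg["temporal_std"].to_numpy(),
        )
        for i, lam in enumerate(curves["lam"]):
            obj_rows.append(
                dict(
                    zip(outer, cell_vals),
                    lam=float(lam),
                    O_CPUE=float(curves["O_CPUE"][i]),
                    O_equity=float(curves["O_equity"][i]),
                    O_stability=float(curves["O_stability"][i]),
                )
            )
    objectives = pd.DataFrame(obj_rows)

    products = {
        "cpue_vs_lambda": cpue_vs_lambda,
        "group_curves": group_curves,
        "lambda_star": lambda_star,
        "objectives": objectives,
    }

    # (d) management comparison, when both kinds were swept
    mgmts = set(agents["management"].unique())
    if {"TAC", "IFQ"} <= mgmts:
        ratio_rows = []
        for (tau_l, depletion), df in group_curves.groupby(
            ["tau_l", "depletion"], sort=True
        ):
            by_mgmt = {m: g for m, g in df.groupby("management")}
            if not {"TAC", "IFQ"} <= set(by_mgmt):
                continue
            row = {"tau_l": tau_l, "depletion": depletion}
            for group in ("top", "bottom"):
                h = {
                    m: float(by_mgmt[m][f"{group}_cpue"].max())
                    for m in ("TAC", "IFQ")
                }
                row[f"{group}_ratio"] = ifq_tac_ratio(h["IFQ"], h["TAC"])
            ratio_rows.append(row)
        products["ifq_tac"] = pd.DataFrame(ratio_rows)

    return products


def require_axis(table: SweepTable, axis: str, at_least: int = 2) -> None:
    """Fail loudly when an analysis needs a grid dimension that was not swept."""
    values = table.seasons[axis].unique()
    if len(values) < at_least:
        raise ValueError(
            f"analysis requires at least {at_least} values on the {axis!r} axis, "
            f"found {len(values)}"
        )
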