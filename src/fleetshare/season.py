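"""Season engine: update ordering, catch-limit management, full runs.

A model run is a single fishing season.  Each timestep applies, in order:

1. school turnover (Poisson death/replacement, emptied schools replaced);
2. sensing for every active agent (local detection beats shared information);
3. information emission from harvesters and resolution by searchers;
4. movement (run-and-tumble search, approach to sensed schools, travel to
   reported locations);
5. harvest settlement in randomised agent order, capped by remaining fish;
6. the management check — TAC closes the fishery once the fleet's collective
   catch reaches ``T``; IFQ retires each agent at its individual quota
   ``T_i = T / N`` and ends when everyone has retired.

All randomness flows through a single ``numpy`` Generator seeded per season,
so a seed reproduces a season bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .agents import (
    AgentParams,
    Mode,
    advance_search,
    nearest_visible_school,
    step_towards,
)
from .sharing import choose_information_targets
from .world import School, StockState, WorldConfig, deplete_school, spawn_school, turnover_step

logger = logging.getLogger(__name__)

__all__ = [
    "ManagementPolicy",
    "SeasonConfig",
    "SeasonResult",
    "SeasonState",
    "init_season",
    "step_season",
    "apply_management",
    "run_season",
    "run_replicates",
    "derive_seeds",
    "write_season_outputs",
]


@dataclass(frozen=True)
class ManagementPolicy:
    """Catch-limit rule for one season.

    ``kind`` is ``"TAC"`` (fleet-wide total allowable catch ``T``) or
    ``"IFQ"`` (individual quota ``T_i = T / n_agents``, agents retire on
    reaching it).  ``t_max`` is a hard time cap guarding against seasons in
    which the limit is unreachable; hitting it logs a warning.
    """

    kind: str
    T: float
    n_agents: int
    t_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("TAC", "IFQ"):
            raise ValueError(f"management.kind must be 'TAC' or 'IFQ', got {self.kind!r}")
        if not (self.T > 0):
            raise ValueError(f"management.T must be > 0, got {self.T}")
        if not (self.n_agents >= 1):
            raise ValueError(f"management.n_agents must be >= 1, got {self.n_agents}")
        if self.t_max is not None and not (self.t_max > 0):
            raise ValueError(f"management.t_max must be > 0, got {self.t_max}")

    @property
    def T_i(self) -> float:
        """Individual quota under IFQ."""
        return self.T / self.n_agents


@dataclass(frozen=True)
class SeasonConfig:
    """Complete, validated parameterisation of one season."""

    world: WorldConfig
    agents: AgentParams
    n_agents: int
    lam: float
    management: ManagementPolicy
    depletion: float = 0.0  # allowed depletion fraction T/P; 0 disables

    def __post_init__(self) -> None:
        if not (self.n_agents >= 1):
            raise ValueError(f"n_agents must be >= 1, got {self.n_agents}")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if not (0.0 <= self.depletion < 1.0 or self.depletion == 1.0):
            raise ValueError(f"depletion must be in [0, 1], got {self.depletion}")
        if self.management.n_agents != self.n_agents:
            raise ValueError("management.n_agents must match n_agents")

    @property
    def stock_P(self) -> float:
        """Total stock implied by the depletion fraction (inf if disabled)."""
        if self.depletion <= 0.0:
            return math.inf
        return self.management.T / self.depletion

    def to_dict(self) -> dict:
        return {
            "world": asdict(self.world),
            "agents": asdict(self.agents),
            "n_agents": self.n_agents,
            "sharing": {"lam": self.lam},
            "management": {
                "kind": self.management.kind,
                "T": self.management.T,
                "t_max": self.management.t_max,
            },
            "depletion": self.depletion,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SeasonState:
    """Full mutable simulation state, advanced by :func:`step_season`."""

    cfg: SeasonConfig
    rng: np.random.Generator
    t: float
    step: int
    schools: list[School]
    next_school_id: int
    stock: StockState
    # fleet arrays, indexed by agent id 0..N-1
    pos: np.ndarray  # (N, 2)
    head: np.ndarray  # (N, 2) unit vectors
    mode: np.ndarray  # (N,) int8, values from agents.Mode
    target_idx: np.ndarray  # (N,) index into schools, -1 if none
    target_id: np.ndarray  # (N,) school id of target, -1 if none
    travel_target: np.ndarray  # (N, 2) reported location while traveling
    catch_total: np.ndarray  # (N,)
    active_time: np.ndarray  # (N,)
    retirement_time: np.ndarray  # (N,) nan until retired
    info_source: np.ndarray  # (N,) sender id, -1 if none
    # per-step logs
    catch_rows: list = field(default_factory=list)
    activity_rows: list = field(default_factory=list)
    stock_trace: list = field(default_factory=list)
    terminated: bool = False
    terminated_by: str = ""


@dataclass
class SeasonResult:
    """Outcome of one season: per-step per-agent catch and activity."""

    config: dict
    config_hash: str
    seed: int
    dt: float
    catch: np.ndarray  # (n_steps, N) catch increments
    activity: np.ndarray  # (n_steps, N) bool, True while not retired
    retirement_times: np.ndarray  # (N,) nan if never retired
    duration: float
    stock_trace: np.ndarray  # (n_steps,) cumulative harvest
    terminated_by: str  # "TAC" | "IFQ" | "t_max"

    @property
    def n_agents(self) -> int:
        return self.catch.shape[1]

    @property
    def n_steps(self) -> int:
        return self.catch.shape[0]

    @property
    def catch_totals(self) -> np.ndarray:
        return self.catch.sum(axis=0)

    @property
    def total_catch(self) -> float:
        return float(self.catch.sum())

    @property
    def active_times(self) -> np.ndarray:
        return self.activity.sum(axis=0) * self.dt


def derive_seeds(master_seed: int, n: int, key: tuple[int, ...] = ()) -> list[int]:
    """Derive ``n`` distinct integer sub-seeds (< 2**31) from a master seed.

    Uses ``numpy.random.SeedSequence`` with an optional spawn key so that
    sweep cells and replicates each get an independent, reproducible stream.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=key)
    raw = ss.generate_state(4 * n + 8, dtype=np.uint64) % (2**31)
    seen: dict[int, None] = {}
    for v in raw.tolist():
        seen.setdefault(int(v))
        if len(seen) == n:
            break
    out = list(seen.keys())
    if len(out) < n:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("seed derivation collision")
    return out


def init_season(cfg: SeasonConfig, seed: int) -> SeasonState:
    """Initialise a season: spawn schools, place agents uniformly at random."""
    rng = np.random.default_rng(seed)
    w = cfg.world
    N = cfg.n_agents
    stock = StockState(
        P=cfg.stock_P,
        cumulative_harvest=0.0,
        depletion_enabled=cfg.depletion > 0.0,
    )
    schools = [
        spawn_school(w, stock, rng, t=0.0, school_id=i) for i in range(w.n_schools)
    ]
    pos = rng.random((N, 2)) * w.L
    ang = rng.random(N) * (2.0 * math.pi)
    head = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return SeasonState(
        cfg=cfg,
        rng=rng,
        t=0.0,
        step=0,
        schools=schools,
        next_school_id=w.n_schools,
        stock=stock,
        pos=pos,
        head=head,
        mode=np.full(N, int(Mode.SEARCHING), dtype=np.int8),
        target_idx=np.full(N, -1, dtype=np.int64),
        target_id=np.full(N, -1, dtype=np.int64),
        travel_target=np.zeros((N, 2)),
        catch_total=np.zeros(N),
        active_time=np.zeros(N),
        retirement_time=np.full(N, np.nan),
        info_source=np.full(N, -1, dtype=np.int64),
    )


def _default_t_max(cfg: SeasonConfig) -> float:
    # emergency cap: many domain crossings per school; prevents non-termination
    # when depletion or a huge T makes the limit unreachable
    w, a = cfg.world, cfg.agents
    return 50.0 * w.n_schools * (w.L / a.v)


def step_season(state: SeasonState) -> SeasonState:
    """Advance the season by one timestep (mutates and returns ``state``)."""
    if state.terminated:
        raise RuntimeError("step_season called on a terminated season")
    cfg = state.cfg
    w, ap, pol = cfg.world, cfg.agents, cfg.management
    rng = state.rng
    N = cfg.n_agents
    L, dt = w.L, w.dt
    mode = state.mode

    # (1) school turnover --------------------------------------------------
    state.schools, state.next_school_id = turnover_step(
        state.schools, w, state.stock, rng, t=state.t, next_id=state.next_school_id
    )
    centers = np.array([s.center for s in state.schools])
    radii = np.array([s.radius for s in state.schools])
    fish = np.array([s.fish for s in state.schools])
    ids = np.array([s.id for s in state.schools])

    active = mode != int(Mode.RETIRED)

    # (2) sensing ----------------------------------------------------------
    sensed = nearest_visible_school(state.pos, centers, radii, fish, ap.r_sense, L)
    sensed[~active] = -1
    has_sense = sensed >= 0

    sel = active & has_sense
    keep_harv = sel & (mode == int(Mode.HARVESTING))
    if keep_harv.any():
        # keep harvesting only on the same (still nearest) school
        keep_harv &= np.where(sel, ids[sensed], -1) == state.target_id
    appr = sel & ~keep_harv
    mode[appr] = int(Mode.APPROACHING)
    state.target_idx[sel] = sensed[sel]
    state.target_id[sel] = ids[sensed[sel]]

    # lost local contact (school died, emptied or moved out of range)
    lost = (
        active
        & ~has_sense
        & ((mode == int(Mode.APPROACHING)) | (mode == int(Mode.HARVESTING)))
    )
    mode[lost] = int(Mode.SEARCHING)
    state.target_idx[lost] = -1
    state.target_id[lost] = -1

    # travelers: drop targets whose school has vanished or been emptied
    trav = active & ~has_sense & (mode == int(Mode.TRAVELING_TO_INFO))
    if trav.any():
        ti = state.target_idx[trav]
        ok = (ids[ti] == state.target_id[trav]) & (fish[ti] > 0.0)
        drop = np.flatnonzero(trav)[~ok]
        mode[drop] = int(Mode.SEARCHING)
        state.target_idx[drop] = -1
        state.target_id[drop] = -1
        state.info_source[drop] = -1

    # (3) information emission and resolution ------------------------------
    harv_idx = np.flatnonzero(mode == int(Mode.HARVESTING))
    recv_idx = np.flatnonzero(
        (mode == int(Mode.SEARCHING)) | (mode == int(Mode.TRAVELING_TO_INFO))
    )
    if cfg.lam > 0.0 and harv_idx.size and recv_idx.size:
        deliver = rng.random((harv_idx.size, recv_idx.size)) < cfg.lam
        if deliver.any():
            sender_locs = centers[state.target_idx[harv_idx]]
            choice = choose_information_targets(
                state.pos[recv_idx], sender_locs, deliver, L
            )
            got = choice >= 0
            who = recv_idx[got]
            src = harv_idx[choice[got]]
            mode[who] = int(Mode.TRAVELING_TO_INFO)
            state.travel_target[who] = sender_locs[choice[got]]
            state.target_idx[who] = state.target_idx[src]
            state.target_id[who] = state.target_id[src]
            state.info_source[who] = src

    # (4) movement ---------------------------------------------------------
    vdt = ap.v * dt
    searching = mode == int(Mode.SEARCHING)
    if searching.any():
        sub_pos = state.pos[searching]
        sub_head = state.head[searching]
        advance_search(sub_pos, sub_head, ap.turn_rate, ap.v, dt, L, rng)
        state.pos[searching] = sub_pos
        state.head[searching] = sub_head
    approaching = mode == int(Mode.APPROACHING)
    if approaching.any():
        tgt = centers[state.target_idx[approaching]]
        state.pos[approaching] = step_towards(state.pos[approaching], tgt, vdt, L)
    traveling = mode == int(Mode.TRAVELING_TO_INFO)
    if traveling.any():
        tgt = state.travel_target[traveling]
        state.pos[traveling] = step_towards(state.pos[traveling], tgt, vdt, L)

    # arrival: approaching agents inside the school radius start harvesting
    if approaching.any():
        ai = np.flatnonzero(approaching)
        d = np.abs(state.pos[ai] - centers[state.target_idx[ai]])
        d = np.minimum(d, L - d)
        inside = np.einsum("ij,ij->i", d, d) <= radii[state.target_idx[ai]] ** 2
        mode[ai[inside]] = int(Mode.HARVESTING)

    # (5) harvest settlement, randomised order ------------------------------
    catch_row = np.zeros(N)
    h_idx = np.flatnonzero(mode == int(Mode.HARVESTING))
    if h_idx.size:
        order = rng.permutation(h_idx) if h_idx.size > 1 else h_idx
        for a in order:
            school = state.schools[state.target_idx[a]]
            _, removed = deplete_school(school, ap.C_q * dt, state.stock)
            catch_row[a] = removed
            state.catch_total[a] += removed
        for a in h_idx:
            if state.schools[state.target_idx[a]].fish <= 0.0:
                mode[a] = int(Mode.SEARCHING)
                state.target_idx[a] = -1
                state.target_id[a] = -1

    state.active_time[active] += dt
    state.catch_rows.append(catch_row)
    state.activity_rows.append(active.copy())
    state.stock_trace.append(state.stock.cumulative_harvest)

    # (6) management check and clock ---------------------------------------
    state.t += dt
    state.step += 1
    apply_management(state)
    return state


def apply_management(state: SeasonState, policy: ManagementPolicy | None = None) -> SeasonState:
    """Apply the catch-limit rule to the current state (mutating).

    TAC terminates the season once the fleet's collective catch reaches
    ``T``; IFQ retires every agent whose ledger has reached ``T_i`` and
    terminates when all are retired.  Either way the season terminates with
    a logged warning at the hard time cap ``t_max``.
    """
    pol = policy if policy is not None else state.cfg.management
    mode = state.mode
    t_max = pol.t_max if pol.t_max is not None else _default_t_max(state.cfg)
    if pol.kind == "TAC":
        if state.catch_total.sum() >= pol.T:
            state.terminated = True
            state.terminated_by = "TAC"
    else:  # IFQ
        newly = (state.catch_total >= pol.T_i) & (mode != int(Mode.RETIRED))
        if newly.any():
            mode[newly] = int(Mode.RETIRED)
            state.retirement_time[newly] = state.t
            state.target_idx[newly] = -1
            state.target_id[newly] = -1
        if (mode == int(Mode.RETIRED)).all():
            state.terminated = True
            state.terminated_by = "IFQ"
    if not state.terminated and state.t >= t_max - 1e-12:
        state.terminated = True
        state.terminated_by = "t_max"
        logger.warning(
            "season hit the time cap t_max=%.6g before the catch limit "
            "(total catch %.6g of T=%.6g)",
            t_max,
            float(state.catch_total.sum()),
            pol.T,
        )
    return state


def _finalize(state: SeasonState, seed: int) -> SeasonResult:
    return SeasonResult(
        config=state.cfg.to_dict(),
        config_hash=state.cfg.config_hash(),
        seed=seed,
        dt=state.cfg.world.dt,
        catch=np.array(state.catch_rows),
        activity=np.array(state.activity_rows, dtype=bool),
        retirement_times=state.retirement_time.copy(),
        duration=state.t,
        stock_trace=np.array(state.stock_trace),
        terminated_by=state.terminated_by,
    )


def run_season(cfg: SeasonConfig, seed: int) -> SeasonResult:
    """Run one full season to termination and return its result."""
    state = init_season(cfg, seed)
    while not state.terminated:
        step_season(state)
    return _finalize(state, seed)


def run_replicates(cfg: SeasonConfig, seeds: Sequence[int]) -> list[SeasonResult]:
    """Run independent replicate seasons, one per seed.

    Seeds must be distinct; each season gets its own random stream, so the
    result list is order-independent (permuting seeds permutes results).
    """
    seeds = [int(s) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise ValueError("run_replicates: seeds must be distinct")
    return [run_season(cfg, s) for s in seeds]


def write_season_outputs(result: SeasonResult, outdir: str | Path) -> None:
    """Write a season as a per-step catch CSV plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = ",".join(str(i) for i in range(result.n_agents))
    np.savetxt(
        outdir / "catch.csv",
        result.catch,
        delimiter=",",
        header=header,
        comments="",
    )
    summary = {
        "seed": result.seed,
        "config_hash": result.config_hash,
        "config": result.config,
        "duration": result.duration,
        "n_steps": result.n_steps,
        "total_catch": result.total_catch,
        "catch_totals": result.catch_totals.tolist(),
        "active_times": result.active_times.tolist(),
        "retirement_times": [
            None if math.isnan(x) else x for x in result.retirement_times.tolist()
        ],
        "terminated_by": result.terminated_by,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
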