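"""Periodic ocean domain, fish-school lifecycle and stock accounting.

The resource landscape is a flat torus of side ``L`` populated by a constant
number of circular fish schools.  Schools die and are replaced at uniformly
random locations following a Poisson process with expected lifespan ``tau_l``
(the inverse of the target species' mobility).  Each school holds a finite,
continuous quantity of fish; harvesting only ever removes fish.  When stock
depletion is enabled, replacement schools spawn with an initial size scaled
down by the fraction of the total stock ``P`` already landed by the fleet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WorldConfig",
    "School",
    "StockState",
    "torus_delta",
    "torus_distance",
    "spawn_school",
    "turnover_step",
    "deplete_school",
]


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and school parameters of the resource landscape.

    Parameters
    ----------
    L : float
        Side length of the periodic square domain.
    n_schools : int
        Number of schools concurrently present (held constant).
    F_s : float
        School radius. Must satisfy ``0 < F_s < L / 2``.
    F_n : float
        Initial fish per school at full stock.
    tau_l : float
        Expected school lifespan; ``math.inf`` disables turnover.
    dt : float
        Simulation timestep. Must resolve the turnover process
        (``dt <= tau_l / 10``).
    """

    L: float
    n_schools: int
    F_s: float
    F_n: float
    tau_l: float
    dt: float

    def __post_init__(self) -> None:
        if not (self.L > 0):
            raise ValueError(f"world.L must be > 0, got {self.L}")
        if not (self.n_schools >= 1):
            raise ValueError(f"world.n_schools must be >= 1, got {self.n_schools}")
        if not (0 < self.F_s < self.L / 2):
            raise ValueError(f"world.F_s must lie in (0, L/2), got {self.F_s}")
        if not (self.F_n > 0):
            raise ValueError(f"world.F_n must be > 0, got {self.F_n}")
        if not (self.tau_l > 0):
            raise ValueError(f"world.tau_l must be > 0, got {self.tau_l}")
        if not (self.dt > 0):
            raise ValueError(f"world.dt must be > 0, got {self.dt}")
        if math.isfinite(self.tau_l) and self.dt > self.tau_l / 10:
            raise ValueError(
                f"world.dt must be <= tau_l/10 to resolve turnover "
                f"(dt={self.dt}, tau_l={self.tau_l})"
            )

    @property
    def death_probability(self) -> float:
        """Per-step school death probability, ``1 - exp(-dt / tau_l)``.

        The exponential clock gives the exact Poisson marginal for any
        timestep, not the first-order approximation ``dt / tau_l``.
        """
        if math.isinf(self.tau_l):
            return 0.0
        return -math.expm1(-self.dt / self.tau_l)


@dataclass
class School:
    """A circular fish school; mutable because harvesting drains it."""

    id: int
    center: np.ndarray  # shape (2,), coordinates in [0, L)
    radius: float
    fish: float
    born_at: float = 0.0


@dataclass
class StockState:
    """Total-stock ledger shared by the whole simulation.

    ``P`` is the total stock available over the season, distinct from the
    fish currently present in the domain.  With depletion enabled, newly
    spawned schools hold ``F_n * max(0, (P - cumulative_harvest) / P)`` fish;
    otherwise the resource renews at full size.
    """

    P: float = math.inf
    cumulative_harvest: float = 0.0
    depletion_enabled: bool = False

    def spawn_fraction(self) -> float:
        """Fraction of ``F_n`` that a newly spawned school receives."""
        if not self.depletion_enabled:
            return 1.0
        return max(0.0, (self.P - self.cumulative_harvest) / self.P)


def torus_delta(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    """Minimal-image displacement vector(s) from ``a`` to ``b``.

    Components are mapped to ``[-L/2, L/2)``; broadcasting over leading
    dimensions is supported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return (b - a + L / 2.0) % L - L / 2.0


def torus_distance(a, b, L: float):
    """Minimal-image Euclidean distance between points on the torus.

    ``a`` and ``b`` are positions (last axis of length 2) in ``[0, L)^2``;
    broadcasting applies.  Raises ``ValueError`` for non-finite coordinates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("torus_distance: non-finite coordinates")
    if not (L > 0):
        raise ValueError(f"torus_distance: L must be > 0, got {L}")
    d = np.abs(a - b)
    d = np.minimum(d, L - d)
    out = np.sqrt(np.sum(d * d, axis=-1))
    return float(out) if out.ndim == 0 else out


def spawn_school(
    cfg: WorldConfig,
    stock: StockState,
    rng: np.random.Generator,
    t: float = 0.0,
    school_id: int = 0,
) -> School:
    """Spawn a school at a uniform random location.

    The initial fish content is ``F_n`` scaled by the stock's remaining
    fraction (1 when depletion is disabled).
    """
    center = rng.random(2) * cfg.L
    fish = cfg.F_n * stock.spawn_fraction()
    return School(id=school_id, center=center, radius=cfg.F_s, fish=fish, born_at=t)


def turnover_step(
    schools: list[School],
    cfg: WorldConfig,
    stock: StockState,
    rng: np.random.Generator,
    t: float = 0.0,
    next_id: int | None = None,
) -> tuple[list[School], int]:
    """Apply one timestep of Poisson school turnover.

    Each school independently dies with probability ``1 - exp(-dt/tau_l)``
    and is immediately replaced by a fresh spawn, keeping the number of
    schools constant.  Fully harvested schools (``fish <= 0``) are replaced
    as if their lifespan had ended, so dead patches never absorb search
    effort.  Returns the updated list (same length, replacements in place)
    and the next unused school id.
    """
    if next_id is None:
        next_id = max(s.id for s in schools) + 1 if schools else 0
    p = cfg.death_probability
    u = rng.random(len(schools))
    out = list(schools)
    for i, s in enumerate(schools):
        if u[i] < p or s.fish <= 0.0:
            out[i] = spawn_school(cfg, stock, rng, t=t, school_id=next_id)
            next_id += 1
    return out, next_id


def deplete_school(
    school: School, amount: float, stock: StockState
) -> tuple[School, float]:
    """Remove up to ``amount`` fish from a school, updating the stock ledger.

    Returns ``(school, removed)`` where ``removed = min(amount, school.fish)``.
    The school is mutated in place; ``stock.cumulative_harvest`` increases by
    exactly the amount removed.
    """
    if amount < 0:
        raise ValueError(f"deplete_school: amount must be >= 0, got {amount}")
    removed = min(amount, school.fish)
    school.fish -= removed
    if school.fish < 0.0:  # guard against rounding
        school.fish = 0.0
    stock.cumulative_harvest += removed
    return school, removed
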