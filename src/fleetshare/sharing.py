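"""Reciprocal information sharing between fishing agents.

Every pair of agents is linked by a reciprocal tie of uniform weight λ (the
fleet-wide consensus level of communication).  While an agent is harvesting,
each searching partner independently receives the school's location with
probability λ per timestep — a λ-weighted continuous broadcast, so λ is
interpretable as the intensity of information flow.  A searcher that has a
school inside its own sensory zone ignores incoming messages (local sensing
wins); otherwise it heads for the nearest reported location.  Retired agents
neither send nor receive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .agents import AgentState, AgentParams, Mode, sense_schools
from .world import School, torus_distance

__all__ = ["SharingNetwork", "InfoMessage", "emit_information", "resolve_information"]


@dataclass(frozen=True)
class SharingNetwork:
    """Complete graph of reciprocal ties with uniform weight λ."""

    n_agents: int
    lam: float
    topology: str = "complete"

    def __post_init__(self) -> None:
        if not (self.n_agents >= 1):
            raise ValueError(f"sharing.n_agents must be >= 1, got {self.n_agents}")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"sharing.lam must be in [0, 1], got {self.lam}")
        if self.topology != "complete":
            raise ValueError("only the complete topology is supported")


@dataclass(frozen=True)
class InfoMessage:
    """A school location reported by a harvesting agent to a searcher."""

    from_agent: int
    school_location: np.ndarray  # shape (2,)
    school_id: int
    issued_at: float = 0.0


def emit_information(
    harvesters: Sequence[AgentState],
    searchers: Sequence[AgentState],
    net: SharingNetwork,
    rng: np.random.Generator,
    t: float = 0.0,
) -> dict[int, list[InfoMessage]]:
    """Draw this step's deliveries for every (harvester, searcher) pair.

    Each pair succeeds independently with probability λ.  Returns a mapping
    from receiving-agent id to its inbox, ordered by sender id.  Harvesters
    must be in ``HARVESTING`` mode with a school target; retired agents are
    excluded on both sides.
    """
    harvesters = sorted(
        (h for h in harvesters if h.mode == Mode.HARVESTING), key=lambda a: a.id
    )
    searchers = [s for s in searchers if s.mode != Mode.RETIRED]
    inboxes: dict[int, list[InfoMessage]] = {s.id: [] for s in searchers}
    if not harvesters or not searchers or net.lam == 0.0:
        return inboxes
    deliver = rng.random((len(harvesters), len(searchers))) < net.lam
    for i, h in enumerate(harvesters):
        school: School = h.target  # type: ignore[assignment]
        for j, s in enumerate(searchers):
            if deliver[i, j]:
                inboxes[s.id].append(
                    InfoMessage(
                        from_agent=h.id,
                        school_location=np.array(school.center, dtype=float),
                        school_id=school.id,
                        issued_at=t,
                    )
                )
    return inboxes


def choose_information_targets(
    recv_positions: np.ndarray,
    sender_locations: np.ndarray,
    deliver: np.ndarray,
    L: float,
) -> np.ndarray:
    """Vectorised nearest-source choice for a batch of receivers.

    ``deliver[i, j]`` says whether sender ``i``'s message reached receiver
    ``j`` this step.  Returns, per receiver, the index of the delivering
    sender whose reported location is nearest (minimal image), or -1 when
    nothing was delivered.  Exact distance ties resolve to the lowest sender
    row index, so callers should order senders by agent id.
    """
    d = np.abs(recv_positions[None, :, :] - sender_locations[:, None, :])
    d = np.minimum(d, L - d)
    D2 = np.einsum("ijk,ijk->ij", d, d)
    D2 = np.where(deliver, D2, np.inf)
    choice = np.argmin(D2, axis=0)
    has = np.isfinite(D2[choice, np.arange(D2.shape[1])])
    return np.where(has, choice, -1)


def resolve_information(
    agent: AgentState,
    inbox: Sequence[InfoMessage],
    schools: Sequence[School],
    params: AgentParams,
    L: float,
) -> AgentState:
    """Decide a searching/traveling agent's response to its inbox.

    Local sensing has priority: with a school in its own sensory zone the
    agent ignores all messages (the season engine then routes it to the
    sensed school).  Otherwise the agent targets the nearest reported
    location, ties broken by lower sender id, and enters
    ``TRAVELING_TO_INFO``.  A traveler with no fresh messages keeps its
    stored target unless that school has vanished or been emptied, in which
    case it reverts to searching.
    """
    if agent.mode not in (Mode.SEARCHING, Mode.TRAVELING_TO_INFO):
        raise ValueError("resolve_information requires a searching or traveling agent")
    if sense_schools(agent, schools, params.r_sense, L) is not None:
        return agent

    if inbox:
        best: Optional[InfoMessage] = None
        best_d = np.inf
        for msg in sorted(inbox, key=lambda m: m.from_agent):
            d = torus_distance(agent.position, msg.school_location, L)
            if d < best_d:
                best, best_d = msg, d
        assert best is not None
        agent.mode = Mode.TRAVELING_TO_INFO
        agent.target = (np.array(best.school_location, dtype=float), best.school_id)
        agent.info_source = best.from_agent
        return agent

    if agent.mode == Mode.TRAVELING_TO_INFO:
        _, school_id = agent.target  # type: ignore[misc]
        still_there = any(s.id == school_id and s.fish > 0.0 for s in schools)
        if not still_there:
            agent.mode = Mode.SEARCHING
            agent.target = None
            agent.info_source = None
    return agent
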