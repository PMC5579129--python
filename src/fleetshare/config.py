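"""Run-configuration files: a JSON dialect with explicit sections.

A run config has sections ``world``, ``agents``, ``sharing``, ``management``
and optional ``depletion`` / ``n_agents``; alternatively a ``scenario`` key
names a frozen scenario from the library, whose world/agent/management
values are merged in before any explicit overrides.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

from .agents import AgentParams
from .season import ManagementPolicy, SeasonConfig
from .world import WorldConfig

__all__ = ["ConfigError", "load_run_config", "run_config_from_dict"]


class ConfigError(ValueError):
    """Malformed run configuration; the message carries the field path."""


def _require(d: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in d:
        raise ConfigError(f"{path}.{key}: missing required field")
    return d[key]


def _section(d: Mapping[str, Any], key: str, path: str = "") -> Mapping[str, Any]:
    val = _require(d, key, path or "config")
    if not isinstance(val, Mapping):
        raise ConfigError(f"{key}: expected an object")
    return val


def run_config_from_dict(data: Mapping[str, Any]) -> SeasonConfig:
    """Build a validated :class:`SeasonConfig` from parsed JSON."""
    data = dict(data)
    if "scenario" in data:
        from .experiments import build_scenario  # late import: avoids a cycle

        scn = build_scenario(data.pop("scenario"))
        merged: dict[str, Any] = {
            "world": dict(vars(scn.world)),
            "agents": dict(vars(scn.agents)),
            "n_agents": scn.n_agents,
            "management": {"kind": "TAC", "T": scn.T, "t_max": scn.t_max},
        }
        for key, val in data.items():
            if isinstance(val, Mapping) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        data = merged

    world_d = _section(data, "world")
    agents_d = _section(data, "agents")
    mgmt_d = _section(data, "management")
    sharing_d = _section(data, "sharing")
    n_agents = _require(data, "n_agents", "config")
    try:
        world = WorldConfig(
            L=float(_require(world_d, "L", "world")),
            n_schools=int(_require(world_d, "n_schools", "world")),
            F_s=float(_require(world_d, "F_s", "world")),
            F_n=float(_require(world_d, "F_n", "world")),
            tau_l=float(_require(world_d, "tau_l", "world")),
            dt=float(_require(world_d, "dt", "world")),
        )
        agents = AgentParams(
            v=float(_require(agents_d, "v", "agents")),
            r_sense=float(_require(agents_d, "r_sense", "agents")),
            C_q=float(_require(agents_d, "C_q", "agents")),
            turn_rate=float(_require(agents_d, "turn_rate", "agents")),
        )
        t_max = mgmt_d.get("t_max")
        management = ManagementPolicy(
            kind=str(_require(mgmt_d, "kind", "management")),
            T=float(_require(mgmt_d, "T", "management")),
            n_agents=int(n_agents),
            t_max=None if t_max is None else float(t_max),
        )
        return SeasonConfig(
            world=world,
            agents=agents,
            n_agents=int(n_agents),
            lam=float(_require(sharing_d, "lam", "sharing")),
            management=management,
            depletion=float(data.get("depletion", 0.0)),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_run_config(path: str | Path) -> SeasonConfig:
    """Load and validate a run configuration file."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be an object")
    return run_config_from_dict(data)
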