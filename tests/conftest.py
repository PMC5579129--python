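"""Shared fixtures: small, fast simulation configurations."""

from __future__ import annotations

import numpy as np
import pytest

from fleetshare import (
    AgentParams,
    ManagementPolicy,
    SeasonConfig,
    WorldConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_world():
    return WorldConfig(L=5.0, n_schools=4, F_s=0.3, F_n=5.0, tau_l=50.0, dt=0.2)


@pytest.fixture
def small_params():
    return AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.1)


def make_season_config(
    *,
    L=5.0,
    n_schools=4,
    F_s=0.3,
    F_n=5.0,
    tau_l=50.0,
    dt=0.2,
    v=1.0,
    r_sense=0.3,
    C_q=1.0,
    turn_rate=0.1,
    n_agents=6,
    lam=0.3,
    kind="TAC",
    T=40.0,
    t_max=500.0,
    depletion=0.0,
) -> SeasonConfig:
    """A small season that terminates in well under a second."""
    return SeasonConfig(
        world=WorldConfig(L=L, n_schools=n_schools, F_s=F_s, F_n=F_n, tau_l=tau_l, dt=dt),
        agents=AgentParams(v=v, r_sense=r_sense, C_q=C_q, turn_rate=turn_rate),
        n_agents=n_agents,
        lam=lam,
        management=ManagementPolicy(kind=kind, T=T, n_agents=n_agents, t_max=t_max),
        depletion=depletion,
    )


@pytest.fixture
def season_config():
    return make_season_config()
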