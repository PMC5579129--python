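"""Agent kinematics, sensing, harvesting and search-time estimation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from fleetshare import (
    AgentParams,
    AgentState,
    Mode,
    School,
    StockState,
    WorldConfig,
    estimate_search_time,
    harvest_step,
    move_towards,
    optimize_turn_rate,
    search_step,
    sense_schools,
    torus_distance,
)
from fleetshare.agents import advance_search, step_towards


def make_agent(pos, heading=(1.0, 0.0)):
    return AgentState(
        id=0, position=np.array(pos, float), heading=np.array(heading, float)
    )


def make_school(center, fish=5.0, radius=0.3, school_id=0):
    return School(id=school_id, center=np.array(center, float), radius=radius, fish=fish)


class TestSensing:
    def test_none_when_out_of_range(self):
        agent = make_agent((1.0, 1.0))
        schools = [make_school((4.0, 4.0))]
        assert sense_schools(agent, schools, r_sense=0.5, L=10.0) is None

    def test_school_at_agent_position(self):
        agent = make_agent((2.0, 2.0))
        schools = [make_school((2.0, 2.0))]
        assert sense_schools(agent, schools, 0.5, 10.0) is schools[0]

    def test_empty_school_is_invisible(self):
        agent = make_agent((2.0, 2.0))
        schools = [make_school((2.0, 2.0), fish=0.0)]
        assert sense_schools(agent, schools, 0.5, 10.0) is None

    def test_nearest_matches_linear_scan(self, rng):
        L, r_sense = 10.0, 1.5
        for _ in range(50):
            agent = make_agent(rng.random(2) * L)
            schools = [
                make_school(rng.random(2) * L, school_id=i) for i in range(8)
            ]
            got = sense_schools(agent, schools, r_sense, L)
            # independent linear scan
            best, best_d = None, math.inf
            for s in schools:
                d = torus_distance(agent.position, s.center, L)
                if d <= r_sense + s.radius and d < best_d:
                    best, best_d = s, d
            assert got is best


class TestSearchStep:
    def test_ballistic_limit_and_speed(self, rng):
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.0)
        agent = make_agent((0.0, 0.0), heading=(0.6, 0.8))
        for k in range(1, 50):
            before = agent.position.copy()
            search_step(agent, params, L=100.0, dt=0.2, rng=rng)
            step = np.linalg.norm(agent.position - before)
            assert step == pytest.approx(params.v * 0.2)
            np.testing.assert_allclose(agent.heading, [0.6, 0.8])

    def test_msd_crosses_from_ballistic_to_diffusive(self):
        """Run-and-tumble: MSD ~ (vt)^2 for t << 1/turn_rate, ~ 4Dt after."""
        rng = np.random.default_rng(7)
        turn_rate, v, dt, L = 1.0, 1.0, 0.05, 1e6
        n, steps = 400, 2000
        pos = np.full((n, 2), L / 2)
        ang = rng.random(n) * 2 * math.pi
        head = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        traj = np.empty((steps + 1, n, 2))
        traj[0] = pos
        for k in range(steps):
            advance_search(pos, head, turn_rate, v, dt, L, rng)
            traj[k + 1] = pos
        def msd(lag_steps):
            disp = traj[lag_steps] - traj[0]
            return float(np.mean(np.sum(disp * disp, axis=1)))
        t_short = 4 * dt  # 0.2 / turn_rate
        assert msd(4) == pytest.approx((v * t_short) ** 2, rel=0.15)
        t_long = 2000 * dt  # 100 / turn_rate
        D = v**2 / (2 * turn_rate)  # 2-D run-and-tumble with full reorientation
        assert msd(2000) == pytest.approx(4 * D * t_long, rel=0.3)


class TestMoveTowards:
    def test_no_movement_at_target(self):
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.0)
        agent = make_agent((3.0, 3.0))
        move_towards(agent, np.array([3.0, 3.0]), params, L=10.0, dt=0.2)
        np.testing.assert_allclose(agent.position, [3.0, 3.0])

    def test_distance_shrinks_by_exactly_one_step(self, rng):
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.0)
        L = 10.0
        for _ in range(30):
            agent = make_agent(rng.random(2) * L)
            target = rng.random(2) * L
            d0 = torus_distance(agent.position, target, L)
            move_towards(agent, target, params, L, dt=0.2)
            d1 = torus_distance(agent.position, target, L)
            assert d1 == pytest.approx(max(d0 - params.v * 0.2, 0.0), abs=1e-9)

    def test_takes_shorter_arc_across_boundary(self):
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.0)
        agent = make_agent((0.2, 5.0))
        move_towards(agent, np.array([9.8, 5.0]), params, L=10.0, dt=0.2)
        # shorter arc goes through x = 0, so x must wrap to ~10.0, not grow
        assert agent.position[0] == pytest.approx(0.0) or agent.position[0] > 9.9

    def test_lands_exactly_on_near_target(self):
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.0)
        agent = make_agent((1.0, 1.0))
        move_towards(agent, np.array([1.1, 1.0]), params, L=10.0, dt=0.2)
        np.testing.assert_allclose(agent.position, [1.1, 1.0])


class TestHarvest:
    def test_constant_rate_and_cap(self):
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.0)
        stock = StockState()
        agent = make_agent((0, 0))
        agent.mode = Mode.HARVESTING
        school = make_school((0, 0), fish=100.0)
        _, _, caught = harvest_step(agent, school, params, stock, dt=0.5)
        assert caught == pytest.approx(0.5)
        assert agent.mode == Mode.HARVESTING

        scraps = make_school((0, 0), fish=0.2)
        _, _, caught = harvest_step(agent, scraps, params, stock, dt=0.5)
        assert caught == pytest.approx(0.2)
        assert agent.mode == Mode.SEARCHING  # exhausted -> back to search

    def test_two_agents_cannot_overdraw(self, rng):
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.0)
        for fish0 in (0.3, 0.7, 5.0):
            stock = StockState()
            school = make_school((0, 0), fish=fish0)
            total = 0.0
            for i in range(2):  # sequential settlement
                agent = make_agent((0, 0))
                agent.mode = Mode.HARVESTING
                _, _, caught = harvest_step(agent, school, params, stock, dt=0.5)
                total += caught
            assert total <= fish0 + 1e-12
            assert stock.cumulative_harvest == pytest.approx(total)


def _first_passage_oracle(world, params, n_trials, seed):
    """Independent scalar-python first-passage simulation (one static school)."""
    rng = np.random.default_rng(seed)
    L, dt = world.L, world.dt
    reach = params.r_sense + world.F_s
    p_turn = -math.expm1(-params.turn_rate * dt)
    times = []
    for _ in range(n_trials):
        cx, cy = rng.random() * L, rng.random() * L
        x, y = rng.random() * L, rng.random() * L
        ang = rng.random() * 2 * math.pi
        t = 0.0
        while True:
            dx = abs(x - cx); dx = min(dx, L - dx)
            dy = abs(y - cy); dy = min(dy, L - dy)
            if dx * dx + dy * dy <= reach * reach:
                times.append(t)
                break
            if rng.random() < p_turn:
                ang = rng.random() * 2 * math.pi
            x = (x + params.v * dt * math.cos(ang)) % L
            y = (y + params.v * dt * math.sin(ang)) % L
            t += dt
    return np.array(times)


class TestSearchTime:
    def test_saturated_domain_gives_zero(self, rng):
        world = WorldConfig(L=5.0, n_schools=3, F_s=1.5, F_n=5, tau_l=50, dt=0.2)
        params = AgentParams(v=1.0, r_sense=6.0, C_q=1.0, turn_rate=0.1)
        est = estimate_search_time(world, params, 100, rng)
        assert est.tau_s_hat == pytest.approx(0.0, abs=1e-6)

    def test_fewer_schools_means_longer_search(self, rng):
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.1)
        many = WorldConfig(L=8.0, n_schools=8, F_s=0.3, F_n=5, tau_l=50, dt=0.2)
        few = WorldConfig(L=8.0, n_schools=4, F_s=0.3, F_n=5, tau_l=50, dt=0.2)
        e_many = estimate_search_time(many, params, 600, rng)
        e_few = estimate_search_time(few, params, 600, rng)
        gap = e_few.tau_s_hat - e_many.tau_s_hat
        assert gap > 2 * math.hypot(e_few.stderr, e_many.stderr)

    def test_consistent_across_seeds(self):
        world = WorldConfig(L=8.0, n_schools=6, F_s=0.3, F_n=5, tau_l=50, dt=0.2)
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.1)
        e1 = estimate_search_time(world, params, 800, np.random.default_rng(1))
        e2 = estimate_search_time(world, params, 800, np.random.default_rng(2))
        assert abs(e1.tau_s_hat - e2.tau_s_hat) < 3 * math.hypot(e1.stderr, e2.stderr)

    def test_matches_independent_first_passage_oracle(self):
        """Static single school: engine estimate vs a scalar re-implementation."""
        world = WorldConfig(
            L=6.0, n_schools=1, F_s=0.4, F_n=5, tau_l=math.inf, dt=0.2
        )
        params = AgentParams(v=1.0, r_sense=0.4, C_q=1.0, turn_rate=0.05)
        est = estimate_search_time(world, params, 500, np.random.default_rng(11))
        oracle = _first_passage_oracle(world, params, 500, seed=12)
        se = math.hypot(est.stderr, oracle.std(ddof=1) / math.sqrt(len(oracle)))
        assert abs(est.tau_s_hat - oracle.mean()) < 3 * se


class TestOptimizeTurnRate:
    def test_single_candidate_is_returned(self, small_world, small_params, rng):
        out = optimize_turn_rate(
            small_world, small_params, candidate_rates=[0.2], n_trials=150, rng=rng
        )
        assert out.turn_rate_star == 0.2
        assert out.tau_s_hat > 0

    def test_rejects_tiny_trial_counts(self, small_world, small_params, rng):
        with pytest.raises(ValueError):
            optimize_turn_rate(
                small_world, small_params, candidate_rates=[0.1], n_trials=10, rng=rng
            )

    def test_optimum_beats_other_candidates_on_fresh_seeds(self):
        world = WorldConfig(L=8.0, n_schools=5, F_s=0.3, F_n=5, tau_l=50, dt=0.2)
        params = AgentParams(v=1.0, r_sense=0.3, C_q=1.0, turn_rate=0.1)
        rates = [0.02, 0.2, 5.0]
        best = optimize_turn_rate(
            world, params, candidate_rates=rates, n_trials=400,
            rng=np.random.default_rng(5),
        )
        fresh = np.random.default_rng(6)
        for r in rates:
            est = estimate_search_time(world, replace(params, turn_rate=r), 400, fresh)
            pooled = math.hypot(best.stderr, est.stderr)
            assert best.tau_s_hat <= est.tau_s_hat + 2 * pooled
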