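"""Catch-rate series, CPUE, objective functions and group statistics."""

import math

import numpy as np
import pytest

from fleetshare import (
    CatchRateSeries,
    catch_rate_series,
    cpue,
    divergence_index,
    ifq_tac_ratio,
    objective_cpue,
    objective_equity,
    objective_stability,
    optimal_lambda,
    percentile_groups,
    run_season,
)
from fleetshare.metrics import objective_scores

from conftest import make_season_config


def fake_result(catch, activity, dt=0.2):
    """Minimal SeasonResult stand-in built from explicit matrices."""
    from fleetshare.season import SeasonResult

    catch = np.asarray(catch, float)
    activity = np.asarray(activity, bool)
    return SeasonResult(
        config={},
        config_hash="",
        seed=0,
        dt=dt,
        catch=catch,
        activity=activity,
        retirement_times=np.full(catch.shape[1], np.nan),
        duration=catch.shape[0] * dt,
        stock_trace=np.cumsum(catch.sum(axis=1)),
        terminated_by="TAC",
    )


def series_from_rates(rates):
    """CatchRateSeries with constant per-window rates per agent row."""
    H = np.asarray(rates, float)
    return CatchRateSeries(H=H, window=1.0, active_time=np.ones_like(H))


class TestCatchRateSeries:
    def test_constant_catch_gives_constant_rate(self):
        res = fake_result(np.full((40, 3), 0.1), np.ones((40, 3)))
        s = catch_rate_series(res, window=1.0)
        np.testing.assert_allclose(s.H, 0.1 / res.dt)

    def test_inactive_windows_are_missing(self):
        catch = np.zeros((40, 2))
        catch[:20, 1] = 0.1
        activity = np.ones((40, 2), bool)
        activity[20:, 1] = False  # retires halfway
        res = fake_result(catch, activity)
        s = catch_rate_series(res, window=2.0)
        assert np.isnan(s.H[1, 2:]).all()
        assert np.isfinite(s.H[1, :2]).all()

    def test_window_ledger_recovers_total_catch(self):
        rng = np.random.default_rng(3)
        catch = rng.random((57, 4)) * 0.1
        res = fake_result(catch, np.ones((57, 4)))
        s = catch_rate_series(res, window=1.8)
        recovered = np.nansum(s.H * s.active_time, axis=1)
        np.testing.assert_allclose(recovered, catch.sum(axis=0), rtol=1e-12)

    def test_rejects_bad_windows(self):
        res = fake_result(np.zeros((10, 2)), np.ones((10, 2)))
        with pytest.raises(ValueError):
            catch_rate_series(res, window=0.05)  # below dt
        with pytest.raises(ValueError):
            catch_rate_series(res, window=100.0)  # beyond season


class TestCpue:
    def test_catch_over_active_time(self):
        res = fake_result(np.full((25, 1), 0.4), np.ones((25, 1)))
        per, fleet = cpue(res)
        assert per[0] == pytest.approx(10.0 / 5.0)
        assert fleet == pytest.approx(2.0)

    def test_identical_agents_have_zero_variance(self):
        res = fake_result(np.full((25, 5), 0.4), np.ones((25, 5)))
        per, _ = cpue(res)
        assert np.std(per) == 0.0


class TestObjectives:
    def test_cpue_direct_evaluation(self):
        by_lam = {
            0.0: [series_from_rates(np.full((3, 4), 2.0))],
            1.0: [series_from_rates(np.full((3, 4), 1.0))],
        }
        scores = objective_cpue(by_lam)
        assert scores[0.0] == 1.0
        assert scores[1.0] == pytest.approx(0.5)

    def test_single_lambda_self_normalises(self):
        assert objective_cpue({0.3: [series_from_rates(np.full((2, 3), 1.7))]}) == {
            0.3: 1.0
        }

    def test_equity_direct_evaluation(self):
        # between-agent stds 2 and 1 -> scores 0.5 and 1
        by_lam = {
            0.0: [series_from_rates([[1.0] * 4, [5.0] * 4])],
            1.0: [series_from_rates([[1.0] * 4, [3.0] * 4])],
        }
        scores = objective_equity(by_lam)
        assert scores[1.0] == 1.0
        assert scores[0.0] == pytest.approx(0.5, rel=1e-6)

    def test_equity_scale_invariant(self):
        base = {
            0.0: [series_from_rates([[1.0] * 4, [5.0] * 4])],
            1.0: [series_from_rates([[1.0] * 4, [3.0] * 4])],
        }
        scaled = {
            lam: [series_from_rates(s.H * 7.0) for s in reps]
            for lam, reps in base.items()
        }
        a, b = objective_equity(base), objective_equity(scaled)
        for lam in a:
            assert a[lam] == pytest.approx(b[lam], rel=1e-6)

    def test_stability_direct_evaluation(self):
        # temporal stds of the fleet-average series: 4 vs 2 -> 0.5 vs 1
        t = np.array([1.0, -1.0, 1.0, -1.0])
        by_lam = {
            0.0: [series_from_rates(np.vstack([10 + 4 * t, 10 + 4 * t]))],
            1.0: [series_from_rates(np.vstack([10 + 2 * t, 10 + 2 * t]))],
        }
        scores = objective_stability(by_lam)
        assert scores[1.0] == 1.0
        assert scores[0.0] == pytest.approx(0.5, rel=1e-6)

    def test_stability_invariant_to_agent_relabelling(self):
        rng = np.random.default_rng(8)
        H = rng.random((5, 6))
        by_lam = {0.0: [series_from_rates(H)], 1.0: [series_from_rates(H * 0.5 + 1)]}
        perm = rng.permutation(5)
        by_lam_p = {
            lam: [series_from_rates(s.H[perm]) for s in reps]
            for lam, reps in by_lam.items()
        }
        assert objective_stability(by_lam) == pytest.approx(
            objective_stability(by_lam_p)
        )

    def test_degenerate_zero_variance_scores_one(self):
        by_lam = {
            0.0: [series_from_rates(np.full((3, 4), 2.0))],  # zero spread
            1.0: [series_from_rates([[1.0] * 4, [2.0] * 4, [3.0] * 4])],
        }
        scores = objective_equity(by_lam)
        assert scores[0.0] == 1.0 and scores[1.0] < 1.0

    def test_max_is_exactly_one_on_simulated_seasons(self):
        results = {
            lam: [run_season(make_season_config(lam=lam), seed) for seed in (1, 2)]
            for lam in (0.0, 0.5, 1.0)
        }
        by_lam = {
            lam: [catch_rate_series(r, window=4.0) for r in reps]
            for lam, reps in results.items()
        }
        sc = objective_scores(by_lam)
        assert max(sc.o_cpue) == 1.0
        assert max(sc.o_equity) == 1.0
        assert max(sc.o_stability) == 1.0
        assert all(0.0 < v <= 1.0 for v in sc.o_cpue + sc.o_equity + sc.o_stability)


class TestPercentileGroups:
    def _results(self, cpues):
        out = []
        for row in cpues:
            row = np.asarray(row, float)
            catch = np.tile(row * 0.2, (10, 1))  # active_time 2.0 -> cpue == row
            out.append(fake_result(catch, np.ones((10, len(row)))))
        return out

    def test_group_sizes_and_bracketing(self):
        results = self._results([np.arange(10.0) + 1.0])
        g = percentile_groups(results, q=0.1)
        assert len(g.top_ids[0]) == 1 and len(g.bottom_ids[0]) == 1
        assert g.bottom_mean[0] <= np.mean(np.arange(10.0) + 1.0) <= g.top_mean[0]

    def test_ties_broken_by_agent_id(self):
        results = self._results([np.ones(10)])
        g = percentile_groups(results, q=0.2)
        assert list(g.bottom_ids[0]) == [0, 1]
        assert list(g.top_ids[0]) == [0, 1]

    def test_rejects_undersized_groups(self):
        results = self._results([np.ones(4)])
        with pytest.raises(ValueError):
            percentile_groups(results, q=0.1)  # N*q < 1
        with pytest.raises(ValueError):
            percentile_groups(results, q=0.7)


class TestOptimalLambdaAndIndices:
    def test_argmax_rules(self):
        rising = {0.0: 1.0, 0.5: 2.0, 1.0: 3.0}
        assert optimal_lambda(rising) == 1.0
        flat = {0.0: 1.0, 0.5: 1.0, 1.0: 1.0}
        assert optimal_lambda(flat) == 0.0  # ties toward smaller λ
        unimodal = {l: -((l - 0.4) ** 2) for l in np.linspace(0, 1, 11)}
        brute = max(unimodal, key=lambda l: (unimodal[l], -l))
        assert optimal_lambda(unimodal) == pytest.approx(brute)

    def test_divergence_examples(self):
        assert divergence_index(0.4, 0.4) == 0.0
        assert divergence_index(0.2, 0.8) == pytest.approx(0.75)
        assert divergence_index(0.0, 0.0) == 0.0
        with pytest.warns(UserWarning):
            assert math.isnan(divergence_index(0.1, 0.0))

    def test_ifq_tac_ratio(self):
        assert ifq_tac_ratio(1.0, 1.0) == 0.0
        assert ifq_tac_ratio(1.2, 1.0) == pytest.approx(0.2)
        r = ifq_tac_ratio(1.3, 0.9)
        assert ifq_tac_ratio(0.9, 1.3) == pytest.approx(1.0 / (1.0 + r) - 1.0)
        with pytest.warns(UserWarning):
            assert math.isnan(ifq_tac_ratio(1.0, 0.0))
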