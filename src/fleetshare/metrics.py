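"""Success metrics: catch-rate series, CPUE, objectives, group analysis.

All metrics derive from the time-resolved catch rate H_i(λ, t) of agent i,
measured on tumbling windows with active-time denominators (effort is the
time an agent spends fishing, so retired agents stop accruing effort).

Three normalised objectives summarise a λ-sweep:

*   O_CPUE(λ)      = avg_i avg_t H_i(λ, t)  /  max_λ (…)
*   O_equity(λ)    = ( std_i avg_t H_i(λ, t)  /  min_λ (…) )⁻¹
*   O_stability(λ) = ( std_t avg_i H_i(λ, t)  /  min_λ (…) )⁻¹

Each equals exactly 1 at the sharing level that optimises it and is smaller
elsewhere, making settings comparable across ecological scenarios.  The
"successful"/"unsuccessful" groups are the top and bottom CPUE percentiles
of each season; their identities reshuffle between seasons because success
here is luck, not skill.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .season import SeasonResult

__all__ = [
    "CatchRateSeries",
    "ObjectiveScores",
    "GroupOptima",
    "PercentileGroups",
    "catch_rate_series",
    "cpue",
    "time_averaged_rates",
    "fleet_rate_series",
    "objective_cpue",
    "objective_equity",
    "objective_stability",
    "objective_curves_from_summaries",
    "percentile_groups",
    "group_cpue_curves",
    "optimal_lambda",
    "divergence_index",
    "ifq_tac_ratio",
]

#: relative scale of the std regularizer used when a λ produces exactly zero
#: variance (degenerate synthetic inputs); keeps the objectives finite while
#: still awarding that λ the maximal score of 1.
EPS_SCALE = 1e-9


@dataclass
class CatchRateSeries:
    """Windowed catch rates H[i, w] with the matching active times."""

    H: np.ndarray  # (N, W) fish/time; NaN where the agent was inactive
    window: float  # nominal window length (time)
    active_time: np.ndarray  # (N, W) time active within each window

    @property
    def activity(self) -> np.ndarray:
        """Active fraction per window (relative to the nominal length)."""
        return self.active_time / self.window


@dataclass(frozen=True)
class ObjectiveScores:
    """The three normalised objectives evaluated on a λ grid."""

    lams: tuple[float, ...]
    o_cpue: tuple[float, ...]
    o_equity: tuple[float, ...]
    o_stability: tuple[float, ...]


@dataclass(frozen=True)
class GroupOptima:
    """CPUE-optimal sharing levels of the success percentiles."""

    lam_plus: float  # optimum of the successful (top) group
    lam_minus: float  # optimum of the unsuccessful (bottom) group

    @property
    def divergence(self) -> float:
        return divergence_index(self.lam_plus, self.lam_minus)


@dataclass
class PercentileGroups:
    """Per-replicate top/bottom CPUE groups (membership reshuffles)."""

    top_ids: list  # list of (k,) arrays, one per replicate
    bottom_ids: list
    top_mean: np.ndarray  # (reps,) group mean CPUE
    bottom_mean: np.ndarray


def catch_rate_series(
    result: SeasonResult, window: float | None = None
) -> CatchRateSeries:
    """Bin a season into tumbling windows of catch rate per agent.

    ``window`` defaults to a fiftieth of the season (never below ``dt``).
    H[i, w] is the agent's catch in the window divided by its active time
    there; windows with no activity are NaN.  The last window may be partial.
    """
    dt = result.dt
    if window is None:
        window = max(result.duration / 50.0, dt)
    if window < dt - 1e-12:
        raise ValueError(f"window ({window}) must be >= dt ({dt})")
    if window > result.duration + 1e-12:
        raise ValueError(f"window ({window}) must be <= season duration")
    w_steps = max(int(round(window / dt)), 1)
    n_steps = result.n_steps
    edges = np.arange(0, n_steps, w_steps)
    catch_w = np.add.reduceat(result.catch, edges, axis=0).T  # (N, W)
    active_w = np.add.reduceat(
        result.activity.astype(float), edges, axis=0
    ).T * dt
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(active_w > 0.0, catch_w / np.where(active_w > 0, active_w, 1.0), np.nan)
    return CatchRateSeries(H=H, window=w_steps * dt, active_time=active_w)


def cpue(result: SeasonResult) -> tuple[np.ndarray, float]:
    """Per-agent CPUE (catch / active time) and the fleet mean.

    Agents with zero active time are flagged NaN (with a warning) and
    excluded from the mean.
    """
    if result.duration <= 0:
        raise ValueError("cpue: season duration must be > 0")
    active = result.active_times
    catch = result.catch_totals
    per_agent = np.where(active > 0.0, catch / np.where(active > 0, active, 1.0), np.nan)
    if np.isnan(per_agent).any():
        warnings.warn(
            "cpue undefined for agents with zero active time; excluded from mean",
            stacklevel=2,
        )
    return per_agent, float(np.nanmean(per_agent))


def time_averaged_rates(series: CatchRateSeries) -> np.ndarray:
    """avg_t H_i: each agent's catch rate averaged over its active windows."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(series.H, axis=1)


def fleet_rate_series(series: CatchRateSeries) -> np.ndarray:
    """avg_i H(t): the fleet-average catch rate per window."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(series.H, axis=0)


def _check_grid(series_by_lam: Mapping[float, Sequence[CatchRateSeries]], least: int):
    if len(series_by_lam) < least:
        raise ValueError(f"need at least {least} λ values, got {len(series_by_lam)}")


def objective_curves_from_summaries(
    lams: Sequence[float],
    mean_rate: Sequence[float],
    between_agent_std: Sequence[float],
    temporal_std: Sequence[float],
) -> dict[str, np.ndarray]:
    """Normalise raw λ-curves into the three objectives.

    ``mean_rate`` etc. are replicate-averaged raw statistics per λ.  This is
    the single normalisation path used both by the series-level objective
    functions and by sweep analysis.
    """
    mean_rate = np.asarray(mean_rate, float)
    eps = EPS_SCALE * float(np.nanmean(mean_rate)) if np.isfinite(mean_rate).any() else EPS_SCALE
    o_cpue = mean_rate / np.max(mean_rate)
    s_between = np.asarray(between_agent_std, float) + eps
    s_temporal = np.asarray(temporal_std, float) + eps
    return {
        "lam": np.asarray(lams, float),
        "O_CPUE": o_cpue,
        "O_equity": np.min(s_between) / s_between,
        "O_stability": np.min(s_temporal) / s_temporal,
    }


def _raw_curves(series_by_lam: Mapping[float, Sequence[CatchRateSeries]]):
    lams = sorted(series_by_lam)
    mean_rate, s_between, s_temporal = [], [], []
    for lam in lams:
        reps = series_by_lam[lam]
        mean_rate.append(
            float(np.mean([np.nanmean(time_averaged_rates(s)) for s in reps]))
        )
        s_between.append(
            float(np.mean([np.std(time_averaged_rates(s), ddof=0) for s in reps]))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            s_temporal.append(
                float(np.mean([np.nanstd(fleet_rate_series(s), ddof=0) for s in reps]))
            )
    return lams, mean_rate, s_between, s_temporal


def objective_cpue(
    series_by_lam: Mapping[float, Sequence[CatchRateSeries]]
) -> dict[float, float]:
    """O_CPUE(λ): fleet-and-time averaged catch rate, normalised to max 1."""
    _check_grid(series_by_lam, 1)
    lams, mean_rate, _, _ = _raw_curves(series_by_lam)
    curves = objective_curves_from_summaries(lams, mean_rate, mean_rate, mean_rate)
    return dict(zip(lams, curves["O_CPUE"].tolist()))


def objective_equity(
    series_by_lam: Mapping[float, Sequence[CatchRateSeries]]
) -> dict[float, float]:
    """O_equity(λ): inverse normalised between-agent std of time-avg rates."""
    _check_grid(series_by_lam, 1)
    lams, mean_rate, s_between, s_temporal = _raw_curves(series_by_lam)
    for lam in lams:
        for s in series_by_lam[lam]:
            if s.H.shape[0] < 2:
                raise ValueError("objective_equity needs at least 2 agents")
    curves = objective_curves_from_summaries(lams, mean_rate, s_between, s_temporal)
    return dict(zip(lams, curves["O_equity"].tolist()))


def objective_stability(
    series_by_lam: Mapping[float, Sequence[CatchRateSeries]]
) -> dict[float, float]:
    """O_stability(λ): inverse normalised temporal std of the fleet rate."""
    _check_grid(series_by_lam, 1)
    lams, mean_rate, s_between, s_temporal = _raw_curves(series_by_lam)
    for lam in lams:
        for s in series_by_lam[lam]:
            if s.H.shape[1] < 2:
                raise ValueError("objective_stability needs at least 2 windows")
    curves = objective_curves_from_summaries(lams, mean_rate, s_between, s_temporal)
    return dict(zip(lams, curves["O_stability"].tolist()))


def objective_scores(
    series_by_lam: Mapping[float, Sequence[CatchRateSeries]]
) -> ObjectiveScores:
    """All three objectives on the λ grid in one pass."""
    lams, mean_rate, s_between, s_temporal = _raw_curves(series_by_lam)
    curves = objective_curves_from_summaries(lams, mean_rate, s_between, s_temporal)
    return ObjectiveScores(
        lams=tuple(lams),
        o_cpue=tuple(curves["O_CPUE"].tolist()),
        o_equity=tuple(curves["O_equity"].tolist()),
        o_stability=tuple(curves["O_stability"].tolist()),
    )


def percentile_groups(
    results: Sequence[SeasonResult], q: float
) -> PercentileGroups:
    """Rank agents by within-season CPUE and cut the top/bottom ``q`` tails.

    Group size is ``ceil(q * N)``; CPUE ties are broken by agent id so groups
    are always full.  Membership is evaluated per replicate season because
    success is stochastic and reshuffles between seasons.
    """
    if not (0.0 < q < 0.5):
        raise ValueError(f"q must be in (0, 0.5), got {q}")
    n = results[0].n_agents
    if n * q < 1.0:
        raise ValueError(f"N*q must be >= 1 (N={n}, q={q})")
    k = math.ceil(q * n)
    ids = np.arange(n)
    top_ids, bottom_ids, top_mean, bottom_mean = [], [], [], []
    for res in results:
        per_agent, _ = cpue(res)
        order_up = np.lexsort((ids, per_agent))  # ascending CPUE, ties by id
        order_down = np.lexsort((ids, -per_agent))  # descending CPUE, ties by id
        bot = order_up[:k]
        top = order_down[:k]
        bottom_ids.append(bot)
        top_ids.append(top)
        bottom_mean.append(float(np.mean(per_agent[bot])))
        top_mean.append(float(np.mean(per_agent[top])))
    return PercentileGroups(
        top_ids=top_ids,
        bottom_ids=bottom_ids,
        top_mean=np.array(top_mean),
        bottom_mean=np.array(bottom_mean),
    )


def group_cpue_curves(
    results_by_lam: Mapping[float, Sequence[SeasonResult]], q: float = 0.1
) -> dict[str, dict[float, float]]:
    """Replicate-averaged top/bottom/fleet CPUE as functions of λ."""
    top: dict[float, float] = {}
    bottom: dict[float, float] = {}
    fleet: dict[float, float] = {}
    for lam in sorted(results_by_lam):
        results = results_by_lam[lam]
        groups = percentile_groups(results, q)
        top[lam] = float(groups.top_mean.mean())
        bottom[lam] = float(groups.bottom_mean.mean())
        fleet[lam] = float(np.mean([cpue(r)[1] for r in results]))
    return {"top": top, "bottom": bottom, "fleet": fleet}


def optimal_lambda(curve: Mapping[float, float]) -> float:
    """Arg-max of a CPUE curve over the λ grid, ties toward smaller λ."""
    best_lam, best_val = None, -np.inf
    for lam in sorted(curve):
        if curve[lam] > best_val:
            best_lam, best_val = lam, curve[lam]
    if best_lam is None:
        raise ValueError("optimal_lambda: empty curve")
    return float(best_lam)


def divergence_index(lam_plus: float, lam_minus: float) -> float:
    """Divergence 1 − (λ+/λ−) between group optima.

    0 means both groups agree on the sharing level.  λ− = 0 with λ+ > 0
    would contradict sharing being (weakly) more attractive to unsuccessful
    agents; it is flagged as undefined (NaN) rather than silently mapped.
    """
    if lam_minus == 0.0:
        if lam_plus == 0.0:
            return 0.0
        warnings.warn(
            "divergence undefined: lam_minus = 0 with lam_plus > 0", stacklevel=2
        )
        return float("nan")
    return 1.0 - lam_plus / lam_minus


def ifq_tac_ratio(h_ifq: float, h_tac: float) -> float:
    """Relative CPUE advantage of IFQ over TAC, ``H_IFQ / H_TAC − 1``.

    Positive values mean the individual-quota system yields better catch
    rates, negative values favour the fleet-wide TAC.  ``H_TAC = 0`` is
    flagged as undefined (NaN).
    """
    if h_tac == 0.0:
        warnings.warn("ifq_tac_ratio undefined: H_TAC = 0", stacklevel=2)
        return float("nan")
    return h_ifq / h_tac - 1.0
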