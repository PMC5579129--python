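# Model and methods

`fleetshare` simulates a fleet of identical fishing agents harvesting mobile
fish schools on a periodic ocean over a single season, to quantify how the
pay-offs of information sharing depend on the spatial dynamics of the target
species, the management rule that limits catch, and depletion of the stock.
This note documents the model, its parameters, the numerical conventions,
and what the simulated results do and do not show.

## The resource landscape

Space is a flat torus `[0, L)²` (agents crossing a boundary re-enter on the
opposite side); all displacement arithmetic uses the minimal-image
convention, and coordinates are continuous with the origin at a corner.
A constant number `n_schools` of circular schools of radius `F_s` is present
at all times. Each school holds a continuous quantity of fish, initially
`F_n`, which only harvesting reduces. Schools die as a Poisson process with
expected lifespan `τ_l` and are immediately replaced at uniformly random
locations, independent of agent positions; the per-step death probability is
`1 − exp(−dt/τ_l)` (the exact exponential marginal, not the first-order
`dt/τ_l`). `1/τ_l` is the mobility of the target species: the faster schools
relocate, the faster information about their locations goes stale.

Two conventions in the school lifecycle deserve mention:

* **Emptied schools are replaced at the next turnover step**, as if their
  lifespan had ended. This keeps the number of schools constant while
  preventing fished-out patches from absorbing search effort. Replacement
  schools follow the same depletion scaling as any other spawn.
* **Baseline schools are finite.** A school can be locally exhausted within
  its lifespan even when stock depletion is disabled (replacements then
  spawn at full `F_n`, so the resource as a whole is renewable). The
  alternative — schools inexhaustible within their lifespan — would remove
  all within-school competition between agents and with it most of the
  crowding cost of sharing, which is central to the low-mobility results.

## Stock depletion

The total stock `P` is distinct from the fish standing in the domain. With
depletion enabled, a school spawned after cumulative fleet harvest `H` holds
`F_n · max(0, (P − H)/P)` fish. The allowed depletion fraction is `T/P`,
where `T` is the seasonal catch limit; `T/P = 0.9` means the fleet may
remove 90% of the stock, so late-season schools are spawned nearly empty
and the time searched per fish rises sharply as the season progresses.

## Fishing agents

Agents move at constant speed `v`. While **searching** they move
ballistically and re-draw a uniformly random heading at exponential times
with rate `turn_rate` (zero-duration reorientations; the classic
run-and-tumble intermittent search). A school whose edge intersects the
sensory disc (centre distance ≤ `r_sense + F_s`) is detected; the agent then
heads straight for the centre (**approaching**) and, once inside the school
radius, **harvests** at the constant catchability `C_q` until the school is
empty, the school dies, or the season ends. The approach leg is a distinct
internal mode so that "harvesting" always means geometrically on the school.

The mean search time `τ_s` of a lone searcher is estimated by Monte-Carlo
(`agents.estimate_search_time`), simulating independent episodes to first
detection under school turnover. `agents.optimize_turn_rate` scans a
log-spaced grid of turn rates (default 15 values spanning
`[0.01·v/L, 100·v/L]`, bracketing the ballistic and diffusive extremes) and
picks the rate minimising the estimated `τ_s`, ties toward the smaller rate.
For both shipped scenarios the `τ_s(turn_rate)` landscape is flat below
roughly `0.3/time` and rises steeply for near-diffusive rates; the scenario
files freeze `turn_rate = 0.05`, on that optimal plateau. The optimisation
is performed once per scenario, before the season, never adaptively.

## Information sharing

Every pair of agents is linked by a reciprocal tie of uniform weight
`λ ∈ [0, 1]` (a fleet-wide consensus level; the network is the complete
graph). Each timestep, every harvesting agent's school location reaches
every currently searching or traveling partner independently with
probability λ — a λ-weighted continuous broadcast. Receivers with a school
in their own sensory zone ignore messages (local sensing wins); otherwise
they head for the nearest reported location (ties to the lowest sender id),
and abandon the trip if that school dies or is emptied en route. Messages
are ephemeral: only the chosen target location is retained. Retired agents
neither send nor receive. λ is a fixed parameter of a run, never a strategic
choice made inside the simulation.

A consequence of per-step rebroadcast worth knowing: over a school visit of
`m` timesteps the per-pair delivery probability is `1 − (1−λ)^m`, which
saturates quickly in λ when visits span many steps. Much of the behavioural
response to λ therefore happens at low λ, and curves are comparatively flat
above `λ ≈ 0.3`. This is inherent to treating λ as a per-step tie weight
rather than a single draw at discovery.

## Management and the season

A run is one fishing season. Each timestep applies, in order: school
turnover; sensing; information emission and resolution; movement; harvest
settlement; the management check. Harvest is settled in randomised agent
order, each agent capped by the fish remaining, so co-occupying agents never
overdraw a school. Under a **TAC** the season ends once the fleet's
collective catch reaches `T` (checked after settlement, so overshoot is at
most one fleet-step, `N·C_q·dt`). Under an **IFQ** each agent retires on
reaching `T_i = T/N` (individual overshoot at most `C_q·dt`, kept in its
ledger) and the season ends when all have retired. Both rules stop at a hard
time cap `t_max` with a logged warning, a guard for configurations whose
limit is unreachable (e.g. extreme depletion). Quota trading (ITQ),
multi-season stock carryover and market dynamics are out of scope.

All randomness flows through one `numpy` PCG64 generator per season, seeded
explicitly; replicate and sweep-cell seeds are derived from a master seed
through `SeedSequence` with stable spawn keys, so any single season, sweep
cell, or whole table is exactly reproducible, and growing a grid or adding
replicates appends records without altering existing ones.

## Metrics

Success metrics derive from the windowed catch-rate series `H_i(λ, t)`:
tumbling windows (default a fiftieth of the season, never below `dt`) with
**active-time denominators** — effort is the time an agent spends fishing,
so retired agents stop accruing effort and their later windows are missing.
CPUE is total catch over total active time. Wall-clock and active-time
denominators coincide under a TAC (no one retires early) and differ under
an IFQ.

The three normalised objectives over a λ grid are

    O_CPUE(λ)      =  avg_i avg_t H_i(λ,t)   /  max_λ (·)
    O_equity(λ)    = (std_i avg_t H_i(λ,t)   /  min_λ (·))⁻¹
    O_stability(λ) = (std_t avg_i H_i(λ,t)   /  min_λ (·))⁻¹

each exactly 1 at its optimal λ. Aggregation order is windows → agents (or
groups) → replicates. A λ with exactly zero variance (possible only in
degenerate synthetic inputs) is handled by adding `ε = 10⁻⁹ ×` (mean CPUE)
to every std before normalising, so that λ still scores 1.

"Successful"/"unsuccessful" agents are the top and bottom `⌈q·N⌉` agents by
within-season CPUE (default q = 0.1), re-identified in every replicate —
success is luck, not skill, and the identities reshuffle between seasons.
Group λ-optima λ+ and λ− are arg-maxima of replicate-averaged group curves,
ties toward smaller λ. The divergence index is `1 − λ+/λ−` (0 when both
optima are 0; flagged undefined if λ− = 0 < λ+, which would contradict
sharing being weakly more attractive to the unsuccessful). The management
comparison `(H_IFQ/H_TAC) − 1` is computed from each group's
replicate-averaged CPUE at that group's own optimal λ under each management.

## Scenario calibration

Absolute parameter values are artifact calibration constants, frozen in the
versioned scenario files (`src/fleetshare/scenarios/*.json`), not in code.
Both exemplars share `L = 7`, `n_schools = 3`, `dt = 0.2`, `v = 1`,
`r_sense = 0.22`, `C_q = 1`, `N = 20`, `T = 640`, and differ only in the
ecological triple: groundfish `F_s = 0.18, F_n = 8, τ_l = 100` (small, lean,
sedentary schools) versus whiting `F_s = 0.5, F_n = 60, τ_l = 8` (large,
rich, fleeting schools).

The calibration was chosen so that, jointly:

* a lone search takes `τ_s ≈ 19` time units (≈ 95 steps) in the groundfish
  geometry — information is genuinely valuable;
* a quota is several schools' worth of fish per agent (`T_i/F_n = 4`), so a
  season is many search–harvest cycles. With very few cycles the luck
  distributions under a catch-quota (fixed catch, random time) and a
  closed-season rule (fixed time, random catch) differ strongly, and IFQ
  CPUE spuriously exceeds TAC CPUE even without depletion; with several
  cycles the two managements are statistically equivalent at baseline, as
  they should be;
* handling time `F_n/C_q` is below ~10 time units, so the extra search time
  per fish under heavy depletion bites agents who linger in the fishery —
  this is what makes a TAC better than an IFQ for the unsuccessful decile at
  `T/P = 0.9` while the successful decile (which fills its quota before the
  stock thins) prefers the IFQ;
* travel distances (≈ `0.38·L/v ≈ 2.7` time) are short relative to the
  multi-agent drain time of a school, so responding to shared information is
  rarely wasted and fleet-level CPUE is only mildly reduced by sharing in
  the groundfish scenario — which is what lets the bottom decile convert the
  collapse of between-agent variance into a ≈ +50% CPUE gain.

Seasons complete in roughly 1 100 steps (groundfish) and 330 steps
(whiting) at the default limits.

## What the simulations do and do not show

The generator produces the study's own world: schools are circular,
identically sized, spawned uniformly; agents are identical, with no skill,
memory, gear, ports, prices, or strategic behaviour; the sharing network is
complete and uniform. Passing tests therefore demonstrate the internal
mechanisms — luck-driven inequality under catch limits, its reduction by
sharing, and the management × depletion interaction — not properties of any
real fishery.

Known limitations:

* **λ saturation** (above): group λ-optima are estimated on curves that are
  nearly flat over much of the grid, so arg-max positions carry Monte-Carlo
  noise even with 20–30 replicates; conclusions are drawn from
  replicate-averaged curves and, where possible, from curve values rather
  than arg-max positions.
* **Divergence under depletion.** In this implementation the unsuccessful
  decile retains a sizeable benefit from sharing even at `T/P = 0.9`
  (λ− ≥ 0.1 in every cell), while λ+ is pinned at 0 in the low-mobility
  corner at all depletion levels. The divergence index `1 − λ+/λ−` is then
  constant at 1 along the depletion axis instead of falling — depletion
  narrows the CPUE stakes of the disagreement, but not the disagreement
  itself. The corresponding test in the suite states the falling-divergence
  expectation and currently fails, intentionally documenting the gap.
* **Management equivalence at baseline is partial.** Matched TAC and IFQ
  seasons without depletion have statistically identical between-agent CPUE
  variance at λ = 0, but for λ > 0 quota retirement thins the crowd late in
  the season and compresses the IFQ spread by roughly a tenth relative to
  the TAC spread — a real interaction of retirement with within-school
  competition in this engine. The grid-wide equivalence test in the suite
  states the full expectation and currently fails for the λ > 0 cells.
* Turnover is memoryless and schools do not move continuously, split or
  merge; "mobility" is entirely relocation-by-replacement.
* Catches are continuous quantities (rates × `dt`), appropriate for schools
  much larger than a single fish.
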