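# fleetshare

Agent-based simulation of a fishing fleet harvesting mobile fish schools on
a periodic ocean, built to study a social–ecological question: **when does
sharing information about fish locations pay off, for whom, and how do
catch-limit management and stock depletion change the answer?**

Identical agents search a torus for circular schools using an intermittent
(run-and-tumble) strategy with an encounter-optimised turn rate. Schools
relocate as a Poisson process with lifespan τ_l (the inverse of species
mobility), hold a finite quantity of fish F_n in a radius F_s, and are
harvested at a constant catchability C_q. While harvesting, an agent's
school location reaches each searching partner with per-step probability λ,
the uniform weight of the fleet's reciprocal social ties. A season ends
under a **TAC** when the fleet's collective catch reaches T, or under an
**IFQ** as each agent retires at its quota T_i = T/N. Optionally the total
stock P is finite and replacement schools shrink in proportion to the
remaining fraction, with depletion severity set by T/P.

Although agents are identical, catch limits turn fishing into a gamble:
within a season some agents are lucky, others are not, and the top and
bottom CPUE deciles (CPUE = catch per unit of time spent fishing) face
different incentives to share. Success of a λ level is scored by three
normalised objectives, each equal to 1 at its optimal λ:

```
O_CPUE(λ)      =  avg_i avg_t H_i(λ,t)  /  max_λ (·)          (collective catch rate)
O_equity(λ)    = (std_i avg_t H_i(λ,t)  /  min_λ (·))⁻¹       (between-agent equity)
O_stability(λ) = (std_t avg_i H_i(λ,t)  /  min_λ (·))⁻¹       (steadiness of landings)
```

where H_i(λ,t) is agent i's windowed catch rate. Two frozen exemplar
scenarios ship with the package: `groundfish` (small, lean, sedentary
schools) and `whiting` (large, rich, fleeting schools), identical in every
fleet parameter.

## Worked example

```python
import fleetshare as fs

scn = fs.build_scenario("groundfish")
cfg = scn.season_config(lam=0.3, management="TAC")
result = fs.run_season(cfg, seed=1)
per_agent, fleet = fs.cpue(result)
print(f"duration {result.duration:.0f}  total catch {result.total_catch:.0f}")
print(f"fleet CPUE {fleet:.3f}  spread {per_agent.min():.3f}-{per_agent.max():.3f}")
```

prints

```
duration 237  total catch 641
fleet CPUE 0.135  spread 0.071-0.191
```

i.e. the 20-agent fleet lands its 640-fish TAC in 237 time units, and even
at moderate sharing (λ = 0.3) the luckiest agent's catch rate is more than
twice the unluckiest's — the within-season inequality the model exists to study.
A λ sweep with replicates, and its reduction to group curves, optima and
objective surfaces:

```python
grid = fs.SweepGrid(lams=(0.0, 0.5, 1.0), replicates=10, master_seed=7)
table = fs.run_sweep(grid, scn)
products = fs.analyze_sweep(table)   # cpue_vs_lambda, group_curves, lambda_star, objectives
```

The same operations are available from a shell:

```
fleetshare scenarios
fleetshare run --config run.json --seed 7 --out out/
fleetshare sweep --scenario groundfish --seed 7 --out sweep/
fleetshare analyze --table sweep/ --out analysis/ --plots
```

## Layout

```
src/fleetshare/
  world.py        periodic domain, school lifecycle, stock accounting
  agents.py       kinematics, sensing, harvest, search-time estimation
  sharing.py      reciprocal information network
  season.py       season engine, TAC/IFQ management, reproducible runs
  metrics.py      H_i(λ,t), CPUE, objectives, percentile groups
  experiments.py  scenario library, sweep driver, figure-level analysis
  scenarios/      frozen exemplar parameterisations (JSON)
docs/methods.md   model description, calibration rationale, limitations
```
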