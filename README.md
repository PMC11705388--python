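# cropswitch

Many-objective optimization of county-level crop switching: can reallocating
the planting areas of staple crops — without touching total cropland in any
county — raise national crop production while lowering nitrogen leaching and
irrigation water use? This package implements the full analysis chain as a
tested, seed-reproducible pipeline on synthetic agro-ecosystem data: it is
aimed at researchers in land-use optimization and agricultural sustainability
who want a transparent, desk-scale testbed for the method rather than a
coupled crop-model study.

## The model

A region of *n* counties grows 7 staple crop groups (rice, maize, wheat,
soybean, peanut, potato, rapeseed) represented by 11 crop functional types
(CFTs). The decision variable is the planting-area matrix `s_ij` (county *i*,
CFT *j*), constrained to each county's fixed cropland area `S_i`:

```
max  F_CP  = (Σ_ij s_ij · y_ij · c_j) · p_sf − p_cp      [kcal]
min  F_LN  =  Σ_ij s_ij · n_ij · ϖ_i^LN                   [kg N]
min  F_IWU =  Σ_ij s_ij · w_ij · ϖ_i^IWU                  [mm·ha]
s.t. Σ_j s_ij = S_i  for every county
```

where `y_ij`, `n_ij`, `w_ij` are per-hectare yield, leached nitrogen and
irrigation demand of CFT *j* in county *i* (the agro-ecological suitability
surface), `c_j` is caloric content, `ϖ_i^LN`/`ϖ_i^IWU` are min–max-normalized
county weights (nitrogen surplus; one minus terrestrial water storage), `p_sf`
is the minimum national self-sufficiency rate across five demand categories
(cereals, soybean, peanut, potato, rapeseed; capped at 1), and `p_cp` penalizes
per-crop production losses against the baseline allocation (total shortfall ×
number of crops losing). Demand itself comes from a log-linear per-capita
calorie model in GDP, with animal calories converted to crop-equivalents by
feed conversion rates and scaled by population.

The search is NSGA-III: per-county fraction genotypes repaired onto the area
simplex, simulated-binary crossover, polynomial mutation, nondominated sorting
with Das–Dennis reference-point niching; the answer is the nondominated set of
the final generation.

On top of optimal allocations, national fertilizer sweeps (0–100 Mt N, step
5 Mt) yield dose–response curves: a logistic `P(t) = K·P0·e^{rt} / (K +
P0·(e^{rt}−1))` for production intensity and a cubic for leached-N intensity.
The marginal return `P′(t)` partitions the rate axis into low / medium / high
fertilization-priority stages; the high stage (`P′ > 30×10³ kcal per kg N`) is
the sustainable fertilization boundary.

All inputs are generated by `cropswitch.synthetic` — there is no external
data dependency. See `docs/methods.md` for the generator's assumptions and
what it does and does not emulate.

## Worked example

```python
import numpy as np
from cropswitch import *
from cropswitch.optimize import crop_production
from cropswitch.accounting import scenario_from_allocation, benefit_report
from cropswitch.demand import DemandSet
from cropswitch.cfts import DEMAND_CATEGORIES, CROP_GROUPS, GROUP_TO_CATEGORY

cfts = build_default_cfts()
region = gen_region(10, 4, seed=1)                      # 10 counties, national-scale area
alloc = gen_baseline_allocation(region, cfts, seed=2)   # historical-style baseline

# fertilization response of the baseline allocation
sweep = sweep_fertilization(alloc, region, cfts)        # 21 levels, 0-100 Mt N
logi, cubic = fit_logistic(sweep), fit_cubic(sweep)
part = partition_priorities(logi, rate_range=(0.0, float(sweep.rate_kg_ha.max())))
gap = fertilization_gap(part, 305.0)

# three-objective optimization against projected demand
suit = gen_suitability(region, cfts, 305.0, seed=3, soil_n_baseline=80.0)
base_cp = crop_production(alloc, suit, cfts)
cat = {c: 1.0 for c in DEMAND_CATEGORIES}
for g, v in zip(CROP_GROUPS, base_cp):
    cat[GROUP_TO_CATEGORY[g]] += 0.9 * float(v)         # demand at 90% of baseline output
demand = DemandSet(year=2020, by_category=cat, per_capita={})
problem = OptimizationProblem(region=region, cfts=cfts, suit=suit,
                              weights=compute_weights(region), demand=demand,
                              baseline_cp_by_crop=base_cp)
sols = evolve(problem, OptimizerConfig(pop_size=100, generations=300, seed=4))
alloc_opt, obj = max(sols, key=lambda s: s[1].f_cp)
rep = benefit_report(scenario_from_allocation(alloc_opt, suit, cfts, "opt"),
                     scenario_from_allocation(alloc, suit, cfts, "base"))
```

This prints (via the obvious format strings):

```
logistic: P0=9.36e+06 kcal/ha  K=2.01e+07 kcal/ha  r=0.0067 /(kg N/ha)  R2=0.989  MRE=1.6%
cubic:    LN(0)=-1.89 kg N/ha  R2=0.9998  MRE=0.8%
sustainable boundary [kg N/ha]: (0.0, 124.1)
baseline 305 kg N/ha is above (distance +180.9)
front size: 100
best-production solution: F_CP=2.232e+15 kcal  p_sf=1.000
national deltas vs baseline: CP +7.4%  LN -10.2%  IWU -19.0%
tradeoff classes: {'co-benefit': 5, 'neutral-nonpositive': 4, 'all-dimension loss': 1}
```

Reading: the baseline allocation's production response saturates at
K ≈ 2.0×10⁷ kcal/ha; marginal returns fall below the high-priority threshold
beyond ≈124 kg N/ha, so a 305 kg N/ha baseline rate over-fertilizes by ≈181
kg N/ha. The optimizer's production-oriented front member raises national
production 7.4% while cutting leached N 10.2% and irrigation water 19.0%,
with 5 of 10 counties achieving strict co-benefits in all three dimensions.
Exact numbers are specific to this seed and the synthetic defaults.

A full multi-step run (generate → demand → optimize → respond → report at
5-year steps) is one call — `run_pipeline(PipelineConfig())` — or from the
shell:

```bash
cropswitch run-all --seed 1 --out my_run
cropswitch generate --seed 1 --out gen && cropswitch respond --run-dir gen \
    --allocation gen/allocation_baseline.csv
```

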