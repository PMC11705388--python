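# Methods

This note documents the models, defaults, and numerical choices behind
`cropswitch`, and what the synthetic study conditions do and do not show.

## The optimization problem

The decision variable is the county × CFT planting-area matrix `s_ij` on the
per-county area simplex (`s_ij ≥ 0`, `Σ_j s_ij = S_i`). Three objectives are
evaluated nationally:

* **Production** `F_CP = rawCP · p_sf − p_cp`, with `rawCP = Σ s_ij y_ij c_j`.
  The self-sufficiency factor `p_sf = min_cat min(1, production/demand)` over
  the five demand categories multiplies production; it is capped at 1 so
  oversupply earns no bonus — it is a penalty, not a reward. The supply-chain
  penalty `p_cp = (Σ shortfalls vs baseline) × (# crops with shortfall)` is
  subtracted in kcal. Both placements are toggleable (`PenaltyConfig`):
  the composition of the two penalties admits more than one algebraic
  reading, and the sensitivity mode (`penalty_sensitivity`) quantifies how
  little the optimal crop shares move when they are reweighted.
* **Leached nitrogen** `F_LN = Σ s_ij n_ij ϖ_i^LN` and **irrigation water**
  `F_IWU = Σ s_ij w_ij ϖ_i^IWU`, with county weights from min–max-normalized
  nitrogen surplus and one minus min–max-normalized terrestrial water
  storage. The weights concentrate environmental pressure where it is
  scarce-resource-relevant; all-identical scores degrade to uniform 0.5 with
  a logged warning.

### NSGA-III implementation

The genotype is the flattened matrix of per-county CFT fractions in [0, 1].
Feasibility is maintained by repair (clip negatives, renormalize each county
row, scale by `S_i`; an all-zero row falls back to uniform), so every
evaluated individual satisfies the area constraint to ~1e-16 relative —
"initially feasible" extends to every generation. Operators: binary
tournament on front rank, simulated-binary crossover (η_c = 15, pair
probability 0.9, per-gene rate 0.5), polynomial mutation (η_m = 20, rate
1/n_genes). Environmental selection is nondominated sorting plus
reference-point niching on the Das–Dennis lattice: objectives are normalized
per generation by the ideal point and the first-front maximum (a simple,
robust nadir estimate), individuals associate to the nearest reference
direction by perpendicular distance, and the last front fills least-crowded
niches first, closest-to-line for empty niches, seeded-random otherwise.
Dominance treats maximization by negating `F_CP`; duplicated points are
mutually non-dominating. The returned answer is the deduplicated rank-1 set
of the final population.

Desk-scale defaults are population 52 × 100 generations with 4 reference
divisions (15 reference points); study-scale settings (1,000 × 3,000) are
plain config values. On a 10-county instance one run takes well under a
second; tests and the multi-step pipeline use budgets between 16 × 5 and
100 × 300 depending on how much convergence the property under test needs
(the random-search dominance audit uses 300 generations, where the final
front is robustly undominated by 10,000 random feasible points across seeds).

## Synthetic agro-ecosystem generator

The generator replaces a process-based vegetation model with the minimal
forms that reproduce the qualitative structure the downstream analysis
assumes:

* **Yield** `y_ij = Ymax_j · exp(−(clim_i + shift − opt_j)²/(2·width_j²)) ·
  f_tot/(f_tot + h_j) · (1+ε)` — Monod response to total nitrogen supply
  `f_tot = f_applied + soil_n_baseline`, times Gaussian climate suitability on
  a normalized [0, 1] coordinate. `Ymax` values are potential yields at the
  climatic optimum under nitrogen saturation (e.g. rice 9.5–11, maize 12–13,
  potato 35 t/ha); half-saturation rates are 85–180 kg N/ha.
* **Leached N** `n_ij = l1_j · f²/(f + l2_j) · (1 + 0.3·(ns_i/mean − 1))` in
  the *applied* rate only: near-quadratic at low rates, asymptotically linear
  — convex everywhere, zero without mineral fertilizer.
* **Irrigation** `w_ij = wcoef_j · aridity_i · (1+ε)`, linear in aridity.
* County covariates follow an order-1 autoregressive pass over county index
  (ρ = 0.6) mapped through the normal CDF — cheap, seedable spatial
  autocorrelation. Areas are lognormal in shape (σ = 0.8) normalized to a
  fixed national-scale total of 1.28×10⁸ ha, so a 10-county toy region
  carries national areas and 0–100 Mt N totals convert to ≈0–780 kg N/ha
  mean rates regardless of county count.
* All noise is multiplicative `(1+ε)` truncated at −0.9, preserving
  non-negativity without rejection sampling; the noise draw depends on the
  seed but not on the fertilizer rate, so monotonicity in fertilizer holds
  realization by realization.

**Soil-N baseline.** `gen_suitability` defaults to a baseline of 0 (pure
mineral-fertilizer response: zero applied N gives zero yield). Response
sweeps and the pipeline default to `soil_n_baseline = 80 kg N/ha`, an
indigenous soil nitrogen supply well within the range reported for
intensively managed croplands. This matters scientifically: with a
realistic soil-N floor, unfertilized production intensity is positive (the
logistic's `P0 > 0`) and the aggregate response is logistic-like — fit
quality R² ≈ 0.99 and mean relative error ≈ 1.6% on the default sweep —
whereas a near-zero floor makes the aggregate strictly Monod-concave and
measurably worse-fitted by a logistic.

**Known structural limitation.** A Monod-type response (with or without the
soil-N floor) has its maximum marginal return at zero applied nitrogen, so
the fitted logistic sits at or past its inflection (`P0 ≳ K/2`) and the
high-priority stage, when non-empty, is an interval `[0, t_hi]` rather than
an interior band. Interior sustainable boundaries of the form `[t_lo, t_hi]`
with `t_lo > 0` arise only from genuinely sigmoidal responses (e.g.
co-limitation at low N), which this generator deliberately does not model;
the partition machinery handles both shapes and is tested on interior-band
logistics directly. The generator likewise omits GCM-ensemble variance
(a single noise dial), process phenology, soil hydrology and daily weather.
Passing tests on this generator demonstrate correctness of the accounting
and optimization machinery under the assumed response structure — not
realism of any particular boundary value.

## Baseline allocation

Per county, CFT fractions are Dirichlet draws with concentration 1 + bias on
the county's three best-yielding CFTs (deterministic yields at the reference
rate 305 kg N/ha; bias 3 by default), emulating historically
suitability-tracking cropping patterns. Bias 0 reduces to symmetric
Dirichlet(1) with mean fraction 1/11.

## Demand model

Per-capita demand in three diet components (crop, animal, empty) is
log-linear in GDP per capita, `demand = α + β·ln(GDP)`, fitted by ordinary
least squares and floored at zero on evaluation. The functional form is the
simplest with diminishing dietary growth in GDP and is isolated behind
`fit_demand_model` / `per_capita_demand` so alternatives can be swapped in.
Animal calories convert via a feed-conversion table (class shares × rates:
dairy/eggs 4, pork 6, poultry 4, ruminant meat 25, seafood 3 crop-kcal per
animal-kcal; all rates ≥ 1 by construction); empty calories (fats, sugars,
alcohol) are excluded from crop demand by default since the optimized staples
do not supply them. National demand = per-capita crop-equivalent × population
× 365, split across the five self-sufficiency categories by a configurable
share vector (default cereals 0.75, soybean 0.12, potato 0.06, peanut 0.04,
rapeseed 0.03). Socio-economic trajectories run on a strict 5-year grid:
noisy-exponential GDP, logistic population.

## Fertilization response and priority stages

Sweeps hold the spatial application pattern fixed (default: proportional to
county area, i.e. a uniform rate) and scale it to each national total (0–100
Mt N, step 5); suitability is regenerated noise-free at the implied
per-county rates and national CP/LN totals are divided by total sown area.
The logistic fit uses nonlinear least squares with initialization P0 = first
sample, K = 1.05 × max, r slope-matched at the rate-range midpoint; the cubic
is ordinary least squares on {t³, t², t, 1}. Fit diagnostics are R² and a
mean relative error defined as Σ|pred−obs| / Σ|obs| — normalized rather than
pointwise, because the zero-fertilizer sample has exactly zero leached-N
intensity and a pointwise relative error is undefined there; the definition
is used uniformly for all fits.

Priority stages threshold the marginal return `P′(t) = r·P·(1−P/K)`:
low < 5×10³, medium 5–30×10³, high > 30×10³ kcal per kg N (config-overridable;
the 10³ scale is the dimensionally consistent one for CP intensities of order
10⁷ kcal/ha saturating over hundreds of kg N/ha). Since `P′` is unimodal with
maximum `rK/4` at the inflection, the high set is found by two bracketed
root solves (Brent) on either side of the inflection: exactly one interval,
boundary included; a threshold above `rK/4` yields an explicitly flagged
empty boundary, and equality degenerates to the single inflection point.
`fertilization_gap` classifies a baseline rate as below/within/above the
boundary with a signed distance to the nearest endpoint.

## Benefit accounting

Benefits are `(optimized − baseline)/baseline × 100` per dimension,
nationally and per county. Tradeoff classes are the eight sign triples of
(ΔCP, ΔLN, ΔIWU) with "+" assigned iff the delta is strictly positive —
exact zeros fall on the "−" side, so (0,0,0) is the neutral-nonpositive
class and a co-benefit county (+,−,−) requires a strict production gain.
Driver attribution differs controlled scenarios: climate effect = baseline −
constant-climate, fertilizer effect = constant-climate − constant-both, and
the combined effect is computed as their sum so additivity is exact in
floating point. Nitrogen use efficiency is harvested N over total N input
(the ratio that makes national values like 0.25 dimensionally coherent).

## Pipeline and formats

All artifacts are plain CSV (one row per county×CFT, 0-based ids, UTF-8, '.'
decimal, a `# seed=...` comment header), YAML configs and JSON summaries; the
manifest records a SHA-256 content hash of the canonicalized config, so the
hash changes iff any field changes. Per-step optimizer seeds derive from the
master seed plus the step index (kept below 2³¹). Each 5-year step is
optimized independently — there is no multi-period coupling — and the
pipeline aborts on the first stage failure with a stage-tagged error.

## Numerical conventions

* Simplex bookkeeping is enforced to 1e-9 relative everywhere it is a
  contract (county areas vs cell sums, allocations vs `S_i`).
* Logistic evaluation clips the exponent at 500 to avoid overflow for
  extreme `r·t`; fitted parameters are bounded positive.
* The exact 3D hypervolume logger sweeps the third objective and accumulates
  2D staircase areas — quadratic in front size, used only for run logs.
* Degenerate inputs fail loudly (zero demand categories, rank-deficient
  design matrices, empty intensity vectors, off-grid years) rather than
  returning defaults.
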