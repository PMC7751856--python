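# Methods

`foodtravel` simulates weekly grocery-shopping travel of household agents in
a disinvested urban neighborhood: who shops where, by which travel mode, and
how far they travel. This note documents the model, its calibration, the
synthetic study conditions, the numerical choices, and what the validation
does and does not establish.

## The model

### Population

The household population is stratified into eight groups by annual household
income (< $20k, $20k–$49,999, ≥ $50k) and householder age (18–44, 45–64,
65+), with the two highest-income older cells merged. A survey sample of
N = 188 households carries the empirical distributions; group sample sizes
are 33, 43, 15, 23, 28, 11, 13 and 22. Income boundaries are half-open
(row 1 is income < 20,000; row 2 is 20,000 ≤ income < 50,000), age columns
closed as printed.

The sample is expanded to the full population (~14.5k households across 23
census tracts) by *sample-based Monte Carlo proportional upscaling*: per
tract, group labels are drawn multinomially from the tract's group mix, and
each synthetic household resamples one respondent record of that group with
replacement. Within-tract group proportions are therefore preserved in
expectation (the stronger of the two readings of "proportional"). Agents are
placed uniformly at random in their tract's houses (houses can hold several
agents), car access is Bernoulli with the group's ownership probability, and
household size is 1 + Poisson(mean − 1) matched to the income-stratum means
(2.20 / 2.37 / 2.56 persons).

### The weekly decision process

Each week an agent draws its number of shopping trips from the group's
trip-count distribution (memoryless across weeks — no pantry state). Each
trip then runs through the decision sequence:

1. **Store-type consideration.** With probability `type_consideration_prob`
   the trip fixes a store type first — the type is a proxy for what
   groceries to buy — drawn from the group's type weights (supermarket-heavy:
   a deliberate grocery run targets a full-line store, while habitual trips
   mix in convenience/dollar visits).
2. **Shopping zone.** The store lies in one of three nested zones:
   the case-study *neighborhood*, the rest of the *city*, or the *suburbs*.
   A trip that fixed its type draws the zone from a type-conditional law
   (chain supermarkets exist only in the suburbs, so chain groceries pull
   the trip out of the city; quick formats keep it nearby); a trip that
   skipped the type decision draws from the complementary habitual law. The
   two laws are solved per group so that their mixture at the group's
   consideration probability equals the group's calibrated zone shares
   *exactly, per trip*. The pool is then the group's reported stores in that
   zone, restricted to the fixed type where the zone offers it (otherwise
   the whole zone pool).
3. **Decision order.** With probability `mode_first_prob` the trip is
   *mode-first*: car owners drive (a hard rule — car access implies the car
   is used for every shopping trip); carless agents draw a mode from the
   group's marginal non-car distribution (bus, taxi, walk, bike), and then
   choose the store with weight ∝ pool weight × exp(−d/λ_mode), where the
   exponential distance decay applies only to walking (λ_walk, default 3 mi)
   and cycling (λ_bike, default 6 mi). Otherwise the trip is *store-first*:
   the store is drawn from the pool weights, and carless agents pick the
   mode from a distance-binned table (1-mile bins, open tail at 10 mi) whose
   motorized share rises with distance.

Each trip record carries the store, mode, motorized flag (car/bus/taxi are
motorized; walking/cycling are not — mixed journeys such as walking out and
taxiing back are collapsed to one primary mode), the shortest-path network
distance from the agent's house, and the store's zone.

### Why zone-stratified store choice

Sampling stores flat from the pool (with zone-block weights rescaled at the
group level) makes each agent's zone probabilities depend on its house and
car status. Group-level zone shares then carry large extra-binomial
variance — with ~260 trips per agent over 52 weeks, even a 0.05
between-agent spread inflates the standard error several-fold — and no
group-level calibration can pin the realized shares to published values at
the precision of millions of trips. Drawing the zone per trip from a
calibrated law makes the zone distribution identical for every trip of a
group, so aggregate shares are exactly binomial around their targets and the
closed-loop validation bound is the true sampling distribution. The cost is
that the distance decay cannot pull a walker's trip into a nearer *zone*
(only to nearer stores within the zone), so a small share of long
non-motorized trips survives in the mode-first branch; the distance taper of
non-motorized travel is produced mainly by the store-first branch's binned
mode tables.

### Why the zone draw conditions on the considered type

The type decision's real-world channel of influence on distance is spatial:
deciding to buy chain-supermarket groceries means driving to the suburbs,
because no chain operates inside the city. With zone and type independent,
that channel is severed and the decision-order parameter (through its
interaction with the distance decay) spuriously dominates the variance of
median distance traveled. The coupled law restores the mechanism; under it
the sensitivity analysis attributes essentially all of the variance of the
median distance to the type-consideration probability, with the
mode-first/store-first split secondary — consistent with the behavioral
interpretation that households decide *what to buy* first.

### Environment

Coordinates are planar, in miles; at the ~20-mile scale of the study area
projected-planar error is negligible and fixtures stay hand-checkable. The
road network is an undirected graph with positive edge lengths; travel cost
is network *distance* (not duration), one-way streets and transit routing
are not modeled. Houses and stores snap to the nearest network node within a
0.25-mile radius; segment offsets are ignored. The origin–destination table
holds the shortest-path distance between every house and every store,
computed by one Dijkstra sweep per distinct store node. Zone polygons are
nested (neighborhood ⊂ city); boundary points belong to the innermost zone
containing them (closed containment), making labels exhaustive and mutually
exclusive. Distances are length-shortest paths; a routing service's
time-shortest paths can differ on real networks.

## Synthetic study conditions

The survey microdata and GIS extracts are not deposited, so the fixtures
module builds a stand-in whose *aggregates* are calibrated to the published
numbers. What the generator emulates:

* **City.** A 12 × 12 mi city containing a ~9.6 sq mi neighborhood of 23
  tracts (~14.5k households, ~630 per tract); a non-uniform grid road
  network (1-mile city blocks, ~0.155-mile blocks inside the neighborhood so
  every house snaps within radius); three mile-spaced arterial corridors
  running east/north into the suburbs. 58 stores sit on network nodes:
  14 neighborhood, 25 city, 19 suburbs, with chain supermarkets only in the
  suburbs and, within each zone, supermarkets toward the far end and
  convenience/dollar formats nearby — the 2008-era condition in which no
  national chain operated inside the city.
* **Sample.** 188 respondents with the exact published stratum sizes; ages
  and incomes uniform within strata; each respondent reports six habitually
  visited stores (zone drawn from the group's zone shares, store within zone
  by a type-level report propensity).
* **Group fixtures.** Store pools and within-zone weights come from the
  respondents' reports. Zone shares, car ownership, trip-count means,
  household sizes and mode tables come from the calibration targets:
  - zone shares: young core-poor 25/57/18 (neighborhood/city/suburbs) and
    medium-income young 11/37/52 as published; the six unpublished groups
    are plausible interpolations rescaled (closed-form, city share absorbs
    the shift) so the trip-weighted population neighborhood share is exactly
    23% and the suburbs carry more than one-third of all trips;
  - no-car shares from 0.58 (young core-poor) down to 0.10 (both ≥ $50k
    groups, "about 10%"), giving a population no-car share ≈ 32% (> 30%).
    Because car owners always drive, a group's non-motorized share is
    bounded by its no-car share, which forces the young core-poor value
    well above the <$20k stratum average;
  - trip-count distributions are Poisson (truncated at 25) with means 5.5
    (young), 5.0 (middle-aged), 3.0 (old) and 8.5 for the medium-income
    young (who shop the most), mixing to ~5.0 trips/household/week;
  - non-car mode tables chosen so the simulated non-motorized trip shares
    fall in the published bands: 40–50% for the young core-poor, 20–40%
    under 5 miles for the core-poor middle-aged, 0–20% for the older
    groups, with the low-income young fully motorized at 6 miles and beyond
    and the medium-income young leveling off below full motorization past
    8 miles.

Everything is seed-deterministic; the packaged study uses fixture seed 42.

What the generator does **not** emulate: real street geometry and
store locations, within-group attribute correlations (income × car × trip
frequency are drawn independently given the group), seasonal or weekly
habit persistence, travel times and transit schedules, and store capacity
or supply effects. Passing the closed-loop tests therefore shows that the
*machinery* (upscaling, OD computation, decision process, reductions)
reproduces known aggregates it was calibrated to — the study's
model-to-model style of partial validation — not that the model predicts
out-of-sample behavior of a real population.

## Sensitivity analysis

The Sobol' engine draws a scrambled 2k-dimensional Sobol' sequence, splits
it into the A / B / AB_i / BA_i cross-sampling blocks (N(2k+2) model runs),
and estimates first-order (S1) and total-order (ST) indices with Jansen
estimators, averaging the mirrored half-designs and attaching percentile
bootstrap intervals over base-sample resamples. The engine is validated
against the analytic variance decomposition of the Ishigami function
(a = 7, b = 0.1) and an additive model at N = 1024, within ±0.05.

The simulator analysis varies four parameters — `mode_first_prob` [0, 1],
`type_consideration_prob` [0, 1], `lambda_walk` [1, 5] mi, `lambda_bike`
[2, 10] mi — applied as global overrides, with the pooled median trip
distance as output. Sobol' indices are variance ratios and robust to
population scale, so the default harness runs 200 sampled agents for 8
weeks, N = 64 base samples, 2 replicates per design point with common
random numbers (identical agent subsample and replicate seeds across design
points); full-scale analysis is a configuration choice. Medians are
computed per trip (matching the distance axis of the mode-by-distance
profiles); per-agent-week totals are available by flag.

## Numerical choices and degenerate inputs

* Per-agent RNG streams are spawned from (simulation seed, agent id), so
  trip logs are invariant to agent iteration order and bit-reproducible.
* Categorical draws use inverse-CDF lookup on cumulative weights; all
  distributions are renormalized on construction (weights must be
  nonnegative with positive sum).
* A type restriction that empties the zone pool falls back to the full zone
  pool, preserving the zone law exactly.
* Distances beyond the last mode-table bin use the open-ended tail bin.
* Median uses the midpoint convention on even counts; empty groups are
  reported absent, never as zero.
* The zone-coupling solve shrinks the type-conditional laws toward the
  group's zone marginal only as far as feasibility requires (a group
  confined to one zone degenerates to uncoupled draws); the packaged groups
  retain full coupling.
* Store-visit maps normalize by the global maximum across groups, per the
  "normalized across all groups" reading; per-group normalization would be
  the alternative.

## Known limitations

* The mode-first branch draws the non-car mode before the store, so
  occasional long walking trips occur in suburb-bound draws; real walkers
  would re-plan. The store-first branch's distance-binned tables carry the
  empirically motivated taper.
* The published "core poor are about three times more likely to lack a car"
  ratio is not reproducible jointly with the 40–50% non-motorized band and
  the always-drive rule; this package follows the band (the ratio lands
  near 4.6).
* A six-fold medium-vs-core-poor suburban trip-rate ratio would require a
  trip mean incompatible with the ~5 trips/week population average under
  the published suburb shares; the packaged conditions give ≈ 4.5×.
* Calibrated aggregates are reproduced in expectation; single runs deviate
  by sampling noise (binomial at the realized trip counts for per-group
  shares; plus multinomial group-mix variance for population-level shares).
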