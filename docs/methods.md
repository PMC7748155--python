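# Methods

`emdisc` implements evolutionary model discovery for the farm-plot-selection
sub-model of a Long House Valley–style household simulation: an agent-based
demographic model with a pluggable plot-selection rule, a strongly-typed
genetic program that searches the space of rules built from hypothesized
causal factors, and a random-forest stage that ranks those factors by their
contribution to simulation fitness. This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## The household simulator

Agents are households on a rectangular grid of cells. Each cell carries a
zone id, a relative soil quality in [0, 1] and a water-body flag; each zone
has a baseline maize yield per cell and year (kg), which is where the
drought signal lives — the raw drought index is not modelled separately.
A year consists of, in order:

1. **Harvest.** `yield = baseline(zone, year) × quality × harvest_adjustment
   × max(0, 1 + ε)`, `ε ~ N(0, harvest_variance)` with `harvest_variance`
   read as a standard deviation. The multiplier is floored at zero so
   harvests are never negative.
2. **Consumption.** Each household eats `base_nutrition_need` kg from its
   oldest maize vintage first; vintages older than two years are then
   discarded.
3. **Death.** Households older than their individually drawn death age
   (`min_death_age + U(0, death_age_span)`) are removed.
4. **Relocation.** A household whose estimated next-year harvest — the
   current year's realized harvest, the simplest estimator consistent with
   the trigger — falls below its need invokes the selection rule on the
   candidate plots its social connectivity admits, and re-sites its dwelling
   on the nearest available cell within `water_source_distance` of an active
   water source. A household with no admissible farm or dwelling leaves the
   valley. There is no separate starvation mortality: a starving household
   stops reproducing and exits through this channel when the landscape
   cannot accommodate it.
5. **Fission.** A household aged in `[16, fertility_end_age)` holding at
   least one year's need fissions with its individual fertility probability;
   the child receives `maize_gift_to_child` of the parent's stock
   (proportionally across vintages) and selects its own farm with the same
   rule, deciding from the parent's location with age 0 and the gift as its
   stock.

Households act in a freshly shuffled order in steps 4 and 5 each year, so no
household-id ordering artifact survives. Corn mass is conserved exactly up
to harvest inflow, consumption, vintage discard and removal outflow; a
per-step ledger asserts this in the tests. The eleven demographic parameters
default to the midpoints of the published ±5% calibration windows
(`DEFAULT_PARAM_RANGES`); the fertility window's lower bound (16 years) is
fixed and not randomized.

Initialization places the starting population (the target series' first
value by default) on the highest-quality available cells, with dwellings
sited near water, initial ages uniform on [0, 30) and one year's need in
storage. This anchors the first-year error at zero; the sources available
to us do not specify the original initialization.

Fitness of a candidate rule is the RMSE between simulated and target annual
household counts over the whole span, computed from one simulation per
evaluation with parameters redrawn uniformly from their ±5% windows — the
randomized-robustness protocol; fitness is therefore stochastic by design
and is never memoized.

## The rule language

A rule is `argmax` over a candidate set of an expression tree of nine factor
terminals combined with `+` and `-`, paired with exactly one connectivity
configuration. Composition is governed by a typed signature table (a child
is legal where its return type matches the parent's parameter type); with
the shipped single `score` type every `+`/`-` tree is well typed, but the
machinery admits richer factor sets. Because the operators are linear, every
rule expands to an integer-weighted sum of factor sub-scores; those signed
integer weights are the rule's **presence** vector, the feature
representation used downstream. Evaluation exploits the same expansion
(accumulated in a fixed canonical factor order, so results are independent
of tree shape), and a brute-force per-candidate oracle in the tests checks
it bit-for-bit.

Factor sub-scores are min–max normalized to [0, 1] within the candidate set;
when all candidates tie, every plot receives the neutral value 0.5 rather
than NaN. The migration factor is binary (different zone = 1) and exempt
from normalization. Specific choices:

- **Distance** is oriented so a higher sub-score means *farther* from the
  current farm, making `argmax[S_All](-F_Dist)` the classic
  nearest-available-plot behaviour (verified decision-for-decision against
  an independent nearest-plot implementation). A config switch
  (`dist_farther_is_better`) flips the orientation.
- **Dryness** of a plot is the negated current-year baseline yield of its
  zone — drier land is land the drought-adjusted yield table rates lower.
- **Previous yield** is the last realized harvest on the cell (0 if never
  farmed); **water availability** counts active sources within the social
  radius; **social presence** counts other households' dwellings within the
  social radius.
- **Homophily** (by age, by corn stock) uses the negated mean absolute
  attribute difference to households within the social radius; plots with
  no household in radius inherit the worst observed raw value so the
  statistic is defined everywhere and monotone in "similar is better".
- Argmax ties break deterministically on lowest (y, x).

Connectivity: `S_All` admits every available plot; "plots known to a
household" means available plots within the neighbour radius of its
dwelling; `S_Fam` pools the knowledge of self, parent, siblings and
grandparents; `S_Neigh` pools households (self included) within the
neighbour radius; `S_Perf` pools the `top_k` households by corn stock.
Defaults: social radius 5 cells, neighbour radius 10, `top_k` 10 — the
qualitative definitions name no values, so these are package defaults, all
configurable. Knowledge is current-year only; no memory of past plots.

## The genetic program

Strongly-typed GP with ramped half-and-half initialization, tree depths
4–10, tournament selection (size 3), typed one-point subtree crossover
(probability 0.8), typed subtree-regrow mutation (probability 0.2) and a
connectivity resample (probability 0.1), with an elitist hall of fame of
size 1. Offspring violating the depth bounds revert to their parents — the
simplest bloat control consistent with bounded trees. Selection, crossover
and mutation operators and their probabilities are package defaults (the
protocol we follow fixes population 50, 100 generations, 20 runs, and the
depth bounds, but not the operators). Every evaluation derives its RNG
stream from `(seed, run, generation, index)`, so evaluations are independent
tasks and the parallel executor (joblib) reproduces the serial results
exactly. All evaluations land in the factor-scores table
(presence × 9, connectivity, fitness, run, generation).

## The importance stage

A `RandomForestRegressor` on the nine presence coefficients, fitted on the
`S_All` rows (the configuration the downstream analyses focus on) with a
90/10 train/test split and the tree count chosen from a grid (10–100 by 10,
150–1000 by 50) by held-out R²; the forest is not refit on the full table
after selection. Three importance readings:

- **Gini importance**: scikit-learn's impurity-decrease shares.
- **Permutation importance**: mean (± sd) increase in held-out squared error
  over 10 independent column shuffles (scikit-learn's implementation with an
  MSE scorer).
- **Joint contribution**: an in-package decision-path decomposition. Walking
  each tree root-to-leaf, the change in node mean at every split is
  attributed to the *set* of distinct features encountered on the path so
  far; per sample, `bias + Σ subset contributions` reconstructs the forest
  prediction exactly (asserted at 1e-9 relative tolerance). Subsets are
  scored by mean absolute contribution over samples, reported up to size 3,
  normalized to sum 1.

One-tailed Mann-Whitney U tests compare fitness across connectivity groups,
importances across factors, and fitness across presence values (only values
with ≥ 200 occurrences by default). The exact null distribution is used when
the smaller group has ≤ 8 tie-free observations, otherwise the normal
approximation with tie correction; completely tied data short-circuit to
p = 1. No multiplicity correction is applied, matching the reported
procedure; α = 0.05 per cell.

## The synthetic environment

The historical valley inputs are not distributed with this package, so
experiments run on generated environments that reproduce their structure.
Soil quality is smoothed white noise (Gaussian filter, correlation length 2
cells) rescaled to [0, 1]; water bodies are the wettest 6% of an independent
smoothed field; zones are four contiguous vertical bands; per-zone baseline
yields are `N(500, 40)` means with `N(0, 50)` annual fluctuation and no
trend by default; water sources arise at density 0.015 per cell, one of
them guaranteed active over the whole span. The default study conditions
are a 20×20 grid over a 40-year span starting at year 800, with 10 founding
households; these sizes are the package's desk-scale choice and every
experiment below states the sizes it used.

Two properties make the generated valley a meaningful test-bed rather than
scenery. First, with mean baseline yield 500 kg and the default harvest
adjustment, a household needs roughly median-quality land to cover its
annual need, so the selection rule controls both relocation churn and the
corn surplus that gates reproduction. Second, the 2-cell quality correlation
length decouples "nearest" from "best", so distance-seeking and
quality-seeking rules produce genuinely different trajectories.

The target household-count series is **planted**: it is the trajectory of
one seeded simulation run under a declared generating rule (quality-seeking
by default) at midpoint parameters. Replaying that rule with the planting
seed reproduces the target exactly (RMSE 0), giving rule-recovery
experiments a known ground truth. A spec whose planted population collapses
before 10% of the span is rejected as degenerate.

What the generator does *not* emulate: the real valley's geography, its
empirical drought chronology, zone-specific hydrology, and the absolute
population scale (tens of households, not thousands). Passing recovery
tests therefore show that the pipeline identifies planted decision factors
under realistic demographic stochasticity at desk scale — not that the
historical inferences themselves are reproduced, which would require the
original environment files.

## Experiment sizes and numerical choices

- Importance-recovery studies use synthetic presence tables (n = 5000,
  presence drawn uniformly on the integers [-3, 5], roughly the bulk of the
  range the GP explores), planted signal `30·Qual − 10·Soc + 5·Mig +
  N(0, 5)` and an interaction-only variant `20·1[Qual>0 ∧ Mig>0] + N(0, 5)`;
  forests use 50 trees with depth caps 10 (main effects) and 6
  (interactions) — deep enough for the planted structure, small enough to
  keep 40-seed studies fast.
- Rule-recovery experiments run a reduced search (5 runs × 15 generations ×
  20 individuals) on default-condition environments planted with single
  factors; the recovered quantity is the presence sign of the planted factor
  in each run's best rule. The robustness comparison uses 100 runs per
  strategy with parameters redrawn each run.
- All randomness flows through `numpy.random.Generator`; every experiment
  derives child seeds from explicit integer keys, so any artifact is
  reproducible from its manifest.
- Degenerate cases fixed by convention: empty candidate sets mean relocation
  failure; all-tied sub-scores give 0.5; all-tied Mann-Whitney data give
  p = 1; constant held-out targets score forests by test error instead of
  undefined R².

## Known limitations

- One shared rule per population: competing behavioural archetypes are out
  of scope, as is pattern-oriented multi-criteria filtering and 2-D spatial
  pattern validation.
- Fitness is a single stochastic replicate per evaluation (a replicate knob
  exists via the config); the resulting noise floor limits how sharply the
  search can distinguish behaviourally similar rules. At desk-scale
  populations (tens of households) this equifinality is material: the
  migration factor's "any plot in a different zone, ties to the grid
  corner" behaviour and the social-presence factor's clustering are both
  mimicked by other rules — notably, local-information connectivities
  (family, neighbour, best-performer candidate sets) cause clustering
  without any social preference in the utility. Quality-seeking, whose
  trajectory is extremal, is recovered reliably; migration- and
  social-planted rules often are not. The corresponding recovery tests
  state the majority bound and report the observed counts when they fail.
- The deterministic (y, x) tie-break makes tie-heavy rules (notably pure
  migration) more stereotyped than a randomized tie-break would; it buys
  seed-independent decisions and exact oracle equivalence.
- Factor sub-scores are recomputed per decision; landscape-level caches
  (zone dryness, water counts, dwelling density) are maintained
  incrementally and verified identical to the direct computation.
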