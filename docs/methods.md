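# Methods

## The optimization problem

A prescription assigns daily servings `X_i ≥ 0` to each food group of a
composition table. Per-serving macronutrient grams give diet totals, and
energy follows from fixed metabolizable-energy factors of 17 kJ/g for
carbohydrate and protein and 36 kJ/g for fat (no alcohol or fibre terms).
Each macronutrient's energy percentage is its own energy contribution over
the total, which makes the three percentages close to 100 identically — a
property the test suite asserts numerically. The objective is the Euclidean
distance, in percentage points, between the achieved and target
(%CHO, %PTN, %FAT) triple; constraints are per-group serving minima `T_i`,
optional maxima, and a total-energy cap at the participant's estimated
energy requirement (EER).

Micronutrient reference-value constraints are deliberately out of scope:
the formulation covers macronutrient-and-energy trials (weight management,
diabetes) only.

### Non-uniqueness and the energy tie-break

Energy percentages are invariant under scaling of the whole diet, so the
problem as stated admits a continuum of equal-distance solutions: any
zero-distance diet remains zero-distance when shrunk toward the serving
minima. We resolve this with a lexicographic secondary objective: among
minimal-distance diets, maximize total energy. The rationale is clinical —
a prescription should meet, not undershoot, the participant's requirement,
and the cap is the only energy anchor in the problem. This is the single
most consequential modeling choice in the package and is surfaced in the
solver diagnostics (`tie_break_applied`).

### Solver

The solve is multi-start SLSQP on the *squared* distance (smooth at the
optimum) with an analytic gradient. Starts are: the serving minima (nudged
off the zero-energy corner if needed), an energy-scaled point partway to
the cap, and seeded random feasible points (default 8, capped at 50). After
the distance phase, a tie-break phase maximizes energy subject to the
squared distance staying within `1e-10` of its optimum, followed by a
polish phase that re-minimizes the distance at the energy level reached, so
the secondary objective can never degrade the primary one. Residual
constraint violations at SLSQP's own tolerance (~1e-5 kJ on the cap) are
removed by shrinking the iterate along the ray from the minima. Convergence
tolerance on the distance is 1e-6 percentage points; infeasibility (serving
minima alone exceeding the cap) is detected up front and reported with the
violating margin.

`brute_force_solve` is an independent grid-enumeration oracle for ≤ 5
groups: it scans `T_i + k·grid` per group (bounded by the configured
maximum or the first grid point whose solo energy exceeds the cap), refuses
grids above 10⁷ points, and applies the same energy-maximal tie-break. The
test suite checks both dominance directions on randomized small instances:
the continuous solve is at least as good as the grid optimum, and snapping
the continuous solution to the grid can never beat the oracle — together,
agreement within one grid step.

### Rounding

Continuous prescriptions are snapped post hoc to each group's increment
(default 0.5 servings; whole servings via the per-constraint `integral`
flag), ties rounding up. Groups with a practical weekly portion mass
(fish, eggs, cheese) are exempt: their fractional daily servings encode
whole weekly portions (0.43/day of 30 g units = one 90 g portion a week)
and snapping would destroy that. A repair pass restores minima and, when
the snapped diet breaches the energy cap, steps the largest upward-rounded
groups back down; if no feasible grid point exists the continuous values
are returned with a warning. The energy change due to rounding is reported.

## Energy requirements

REE uses the Mifflin-St Jeor equations (kcal/day) on weight (kg), height
(cm) and age (years), with the sex difference a constant 166 kcal (the gap
between the +5 and −161 intercepts). EER = REE × PA. The PA menu ships
sedentary 1.2, light 1.6 (default), moderate 1.75, very active 1.9; only
the default is load-bearing. The equations are calorie-denominated while
the diet models are framed in kJ; we convert at the thermochemical
1 kcal = 4.184 kJ and carry both units at full precision — EER is never
rounded to a 500-kJ increment before the solve, since the point of an
automated tool is exact individual tailoring.

## Study configuration

The bundled `table1_default` config encodes the validation constraint set:
vegetables ≥ 5, whole grains ≥ 4, fruits in [2, 4), sugar ≤ 3, low-fat
milk/yoghurt ≥ 2.5, whole milk and whole soy milk excluded, lean meat
(30 g) ≥ 3, cheese/eggs/spread-fats free, oily fish ≥ 0.43/day, with a
high-energy variant (inclusive at 8500 kJ, per the printed 8500–10,000 kJ
band) raising the lean-meat minimum to 5 and lifting the sugar cap. Two
encoding choices are worth noting. First, groups whose source notation is
ambiguous between "integer-valued" and "no upper limit" are encoded per the
accompanying footnote as unbounded above, with the integer reading
available as an opt-in `integral` flag. Second, the strict fruit bound
"< 4" is realized by the solver as `4 − increment` (3.5 at the default
half-serving grid). Overrides (`apply_override`) are pure functions:
removing a group and replacing it (the vegetarian meat → meat-alternatives
swap) never mutates the trial defaults, so the next participant starts
clean.

## Group statistics and screening

Within-group dispersion uses the sample (n−1) standard deviation — groups
are treated as samples of the wider food supply; a single-item group has
SD = 0 by convention. CV = SD/mean × 100 is screened against a *strict*
15 % threshold; zero-mean nutrients have no CV and are flagged for manual
comparison against published exchange lists rather than auto-passed.
Primary-source ranking orders groups by descending contribution and
returns the longest prefix whose cumulative share stays strictly below the
75 % cutoff; a single dominant group yields an empty prefix with a warning.
Item-level data are stored per 100 g and converted to per-serving via
`serving_size_g / 100` at the point of use.

## Comparison metrics

Percent difference is asymmetric by design — the denominator is always the
reference method (the experienced-dietitian manual model). Cells are
rounded to the nearest integer, half away from zero, and computed from
unrounded servings when available: 0.286 vs 0.58 gives 51, whereas
pre-rounded 0.29 would give 50, so full precision is carried internally and
rounding happens only at display. The weekly-frequency conversion
`servings/day × 7 × unit_g / portion_g` is exposed generically; the egg
fixture encodes a 60 g practical unit, since a 30 g unit cannot reproduce
consistent whole-egg weekly counts.

## Synthetic fixtures

No public food-composition or pooled-trial intake database backs this
package, so fixtures are generated. Group archetypes carry plausible
exchange-list-style per-serving means for the default roster (vegetables,
whole grains, fruits, sugar, dairy, lean meat, cheese, eggs, oily fish,
mono- and polyunsaturated spread fats). Item pools are drawn with
multiplicative log-normal noise — keeping nutrient masses positive — then
linearly recentred so every group's sample CV (n−1) hits the requested
target exactly; the group's representative profile is the item mean, so
table and items are mutually consistent. Participant rosters draw uniform
anthropometry from configurable ranges (defaults 20–85 y, 140–200 cm,
40–120 kg) with two deterministic anchor participants at the extremes, so
the default roster's EERs bracket the 5000–10,000 kJ comparison band by
construction. Everything is a pure function of the fixture spec including
its seed; regenerated files are byte-identical.

What the fixtures do **not** emulate: real measured compositions,
between-nutrient correlation within items, skew beyond log-normal, or the
consumption-frequency weighting of real trial intake data. Passing tests
therefore demonstrate the correctness of the arithmetic, the solver and
the screening logic under controlled conditions — not agreement with any
real food supply. In particular, absolute serving outputs on real trial
food tables cannot be reproduced here; validation of the solver is
property-based (feasibility, oracle agreement, exact recovery on the
analytically solvable pure-macronutrient instance where the optimum
(10, 4, 5.667) servings at a 3400 kJ cap is known in closed form).

## Problem sizes and determinism

The randomized suites use 500 instances (3–6 groups) for feasibility and
100 small instances (2–3 groups, caps kept low so oracle grids stay under
~10⁶ points at the half-serving grid) for oracle agreement; both complete
in seconds. All randomness in the library, tests and acceptance script is
seeded; `solve` is deterministic for a fixed `(config, table, EER, seed)`.

## Known limitations

- Macronutrients only; no vitamins, minerals, fibre or alcohol.
- Day-level prescriptions; no meal scheduling.
- The energy tie-break is a modeling convention, not an observed rule of
  any reference implementation.
- The high-energy adjustment keys on the two group ids it names
  (`lean_meat`, `sugar`); custom rosters wanting the rule must reuse those
  ids or apply their own override.
- Infeasibility reporting covers the energy cap vs minima; pairwise
  incompatible bounds are caught at config validation instead.
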