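# dietmodel

Individualized dietary prescriptions for clinical trials by constraint
optimization over food-group servings.

## The problem

Dietary randomized controlled trials need every participant's background
diet standardized to the trial's targets — typically a macronutrient energy
split such as 50 % carbohydrate / 20 % protein / 30 % fat — while respecting
food-based guidance (at least 5 servings of vegetables a day, at most one
fish portion a week, ...) and each participant's own energy requirement.
Done by hand in a spreadsheet this is slow and user-dependent. `dietmodel`
automates it: given a food-group composition table, the trial's targets and
per-group serving constraints, and a participant's anthropometry, it
computes the daily serving prescription closest to the trial targets.

## The model

Let `X_i` be the daily servings of food group `i`, with per-serving
macronutrient grams `cho_i, ptn_i, fat_i`. Diet totals are

```
TotalCHO = Σ X_i·cho_i   TotalPTN = Σ X_i·ptn_i   TotalFAT = Σ X_i·fat_i
TotalEnergy = 17·TotalCHO + 17·TotalPTN + 36·TotalFAT    (kJ)
```

with `%CHO = 17·TotalCHO / TotalEnergy × 100` (and likewise each
macronutrient from its own total), so `%CHO + %PTN + %FAT = 100` always.
The solver minimizes the Euclidean distance

```
d = √( (%CHO − TargetCHO)² + (%PTN − TargetPTN)² + (%FAT − TargetFAT)² )
```

subject to `X_i ≥ T_i` (the trial's per-group serving targets, plus any
maxima) and `TotalEnergy ≤ EER`. The energy cap comes from the
Mifflin-St Jeor resting energy expenditure
(`REE = 9.99·weight + 6.25·height − 4.92·age − 161` for females, `+5`
instead of `−161` for males, kcal/day) scaled by a physical-activity factor
(default 1.6, light activity) and converted at 4.184 kJ/kcal. Among
equal-distance diets the solver prefers the one of highest total energy, so
prescriptions approach the participant's requirement from below instead of
undershooting it.

Around the solve, the package provides the supporting workflow: food-table
and item-level CSV I/O, within-group homogeneity screening
(CV = SD/mean × 100 against a strict 15 % threshold), primary-source
ranking, per-participant constraint overrides (vegetarian swaps, the
high-energy constraint variant at ≥ 8500 kJ), rounding of prescriptions to
practical half-serving grids, method-vs-reference percent-difference
reports, and a seeded synthetic fixture generator.

## Worked example

Generate a synthetic study fixture and model one participant:

```
$ dietmodel synth --preset realistic --seed 7 --out fx --participants 4
$ dietmodel model --study table1_default --foods fx/foods.csv \
      --sex female --age 30 --height 165 --weight 60 --seed 1
status: optimal  (EER cap 8850.3 kJ)
distance: 0.0000 percentage points
energy: 8850.3 kJ  %CHO 50.00  %PTN 20.00  %FAT 30.00
group,servings,rounded
vegetables,5.3499,5.5000
whole_grains,7.5183,7.5000
fruits,3.4930,3.5000
sugar,6.5122,6.5000
milk_yoghurt_low_fat,3.6447,3.5000
...
lean_meat,5.0210,5.0000
oily_fish,0.4514,0.4514
```

The 30-year-old, 165 cm, 60 kg female participant has
REE = 1322.05 kcal/day, hence EER = 1322.05 × 1.6 = 2115.28 kcal/day
= 8850.33 kJ/day. Because her EER exceeds 8500 kJ the high-energy constraint
variant applies (lean-meat minimum 5, sugar cap lifted); the solver then
finds a diet hitting the 50/20/30 split exactly (`distance: 0.0000`) at the
energy cap. Servings are reported both continuous and rounded to the
half-serving grid; weekly-frequency groups such as oily fish stay
continuous (0.4514 servings/day of 30 g units ≈ one 90 g portion a week).

Other subcommands: `dietmodel eer` (energy requirement only),
`dietmodel stats` (group CV screening), `dietmodel pipeline` (whole roster
with a run manifest), `dietmodel compare` (percent-difference tables
against a reference model).

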