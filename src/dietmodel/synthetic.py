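"""Seeded synthetic fixtures: food tables, item pools and participant rosters.

The production tool drew on two private data sources - a national food
composition database and pooled baseline intake data from completed
trials - neither of which is redistributable. This module generates
self-contained stand-ins with the same shape: a food-group roster modeled
on the default constraint set (vegetables, whole grains, fruits, dairy,
lean meat, cheese, eggs, oily fish, spread fats, ...), item pools with a
controlled within-group coefficient of variation, and participant rosters
whose energy requirements span the 5000-10,000 kJ comparison bands.

Item noise is multiplicative log-normal (keeps nutrient masses positive),
then linearly recentred so each group's sample CV hits the requested
target exactly; the archetype means are plausible exchange-list-style
values, not measurements. A deterministic "exactly solvable" table of
pure-macronutrient groups is also provided: for it the optimizer's
zero-distance serving vector is known in closed form.

Everything is a pure function of the spec (including its seed), so
regenerated fixtures are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .energy import (
    ActivityLevel,
    DEFAULT_ACTIVITY,
    Participant,
    Sex,
    write_participants,
)
from .foodspec import (
    FoodGroup,
    FoodItem,
    FoodTable,
    Nutrient,
    NutrientProfile,
    ValidationFailure,
    write_food_items,
    write_food_table,
)
from .studyconfig import (
    MacroTargets,
    ServingConstraint,
    StudyConfig,
    save_study_config,
    table1_default,
)

__all__ = [
    "FixtureSpec",
    "ARCHETYPES",
    "generate_food_table",
    "generate_participants",
    "pure_macro_table",
    "pure_macro_config",
    "PURE_MACRO_EER_KJ",
    "PURE_MACRO_OPTIMUM",
    "write_fixture",
]


class _Archetype(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    serving_size_g: float
    cho_g: float  # per-serving means
    ptn_g: float
    fat_g: float
    weekly_unit_g: Optional[float] = None


#: per-serving archetype means for the default roster; loosely
#: exchange-list-shaped fixture values, not measured compositions
ARCHETYPES: dict[str, _Archetype] = {
        "vegetables": _Archetype(
            name="Vegetables", serving_size_g=75, cho_g=3.5, ptn_g=1.5, fat_g=0.2
        ),
        "whole_grains": _Archetype(
            name="Whole grains", serving_size_g=40, cho_g=15, ptn_g=3, fat_g=1.2
        ),
        "fruits": _Archetype(
            name="Fruits", serving_size_g=120, cho_g=15, ptn_g=0.6, fat_g=0.2
        ),
        "sugar": _Archetype(
            name="Sugar", serving_size_g=5, cho_g=5, ptn_g=0.0, fat_g=0.0
        ),
        "milk_yoghurt_low_fat": _Archetype(
            name="Milk/yoghurt (low fat)",
            serving_size_g=250,
            cho_g=12,
            ptn_g=8.5,
            fat_g=2.5,
        ),
        "milk_yoghurt_whole": _Archetype(
            name="Milk/yoghurt (whole)",
            serving_size_g=250,
            cho_g=12,
            ptn_g=8,
            fat_g=9.5,
        ),
        "soy_milk_whole": _Archetype(
            name="Soy milk (whole)", serving_size_g=250, cho_g=9, ptn_g=8, fat_g=8
        ),
        "lean_meat": _Archetype(
            name="Lean meat (30 g)", serving_size_g=30, cho_g=0.0, ptn_g=7, fat_g=1.2
        ),
        "cheese": _Archetype(
            name="Cheese (reduced fat, 30 g)",
            serving_size_g=30,
            cho_g=0.3,
            ptn_g=7.5,
            fat_g=6,
            weekly_unit_g=30,
        ),
        "eggs": _Archetype(
            name="Eggs (1 egg)",
            serving_size_g=60,
            cho_g=0.4,
            ptn_g=6.3,
            fat_g=5.3,
            weekly_unit_g=60,
        ),
        "oily_fish": _Archetype(
            name="Oily fish (30 g units)",
            serving_size_g=30,
            cho_g=0.0,
            ptn_g=7,
            fat_g=3,
            weekly_unit_g=90,
        ),
        "mufa": _Archetype(
            name="Monounsaturated spread/oil (tsp)",
            serving_size_g=5,
            cho_g=0.0,
            ptn_g=0.0,
            fat_g=5,
        ),
        "pufa": _Archetype(
            name="Polyunsaturated spread/oil (tsp)",
            serving_size_g=5,
            cho_g=0.0,
            ptn_g=0.0,
            fat_g=5,
        ),
}


class FixtureSpec(BaseModel):
    """Parameters of a synthetic fixture (fully determined by its seed)."""

    model_config = ConfigDict(frozen=True)

    group_ids: tuple[str, ...] = tuple(ARCHETYPES)
    items_per_group: int = Field(default=8, ge=2)
    cv_target_pct: float = Field(default=10.0, ge=0)
    n_participants: int = Field(default=40, ge=1)
    age_range_y: tuple[float, float] = (20.0, 85.0)
    height_range_cm: tuple[float, float] = (140.0, 200.0)
    weight_range_kg: tuple[float, float] = (40.0, 120.0)
    female_fraction: float = Field(default=0.5, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        unknown = [g for g in self.group_ids if g not in ARCHETYPES]
        if unknown:
            raise ValueError(f"unknown archetype group(s): {', '.join(unknown)}")
        for name in ("age_range_y", "height_range_cm", "weight_range_kg"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} empty or non-positive: ({lo:g}, {hi:g})")
        return self


def _calibrated_values(
    mean: float, cv_pct: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n positive draws whose sample mean is ``mean`` and sample CV ``cv_pct``.

    Log-normal draws are recentred and rescaled linearly so the sample
    statistics hit the target exactly (n-1 denominator).
    """
    if mean == 0 or cv_pct == 0:
        rng.standard_normal(n)  # burn draws so the stream stays aligned
        return np.full(n, mean, dtype=float)
    cv = cv_pct / 100.0
    sigma = np.sqrt(np.log1p(cv**2))
    raw = rng.lognormal(mean=np.log(mean) - sigma**2 / 2.0, sigma=sigma, size=n)
    s = raw.std(ddof=1)
    if s == 0:
        raise ValidationFailure("degenerate draws; increase items_per_group")
    vals = mean + (raw - raw.mean()) * (cv * mean / s)
    if np.any(vals <= 0):
        raise ValidationFailure(
            f"CV target {cv_pct:g}% unreachable with positive values at "
            f"n={n}; lower the target or raise items_per_group"
        )
    return vals


def generate_food_table(spec: FixtureSpec) -> tuple[FoodTable, list[FoodItem]]:
    """Generate a food-group table and its item pool.

    Per group, ``items_per_group`` items are drawn around the archetype's
    per-100 g means with the requested within-group CV (exact, per
    nutrient); the group's representative per-serving profile is the item
    mean rescaled to the serving mass, so group statistics computed from
    the items are consistent with the table by construction.
    """
    rng = np.random.default_rng(spec.seed)
    groups: list[FoodGroup] = []
    items: list[FoodItem] = []
    for gid in spec.group_ids:
        arch = ARCHETYPES[gid]
        scale = 100.0 / arch.serving_size_g
        means_100g = {
            Nutrient.CHO: arch.cho_g * scale,
            Nutrient.PTN: arch.ptn_g * scale,
            Nutrient.FAT: arch.fat_g * scale,
        }
        draws = {
            nut: _calibrated_values(m, spec.cv_target_pct, spec.items_per_group, rng)
            for nut, m in means_100g.items()
        }
        for k in range(spec.items_per_group):
            items.append(
                FoodItem(
                    item_id=f"{gid}_{k:02d}",
                    group_id=gid,
                    profile_per_100g=NutrientProfile(
                        cho_g=float(draws[Nutrient.CHO][k]),
                        ptn_g=float(draws[Nutrient.PTN][k]),
                        fat_g=float(draws[Nutrient.FAT][k]),
                    ),
                )
            )
        per_serving = {
            nut: float(v.mean()) / scale for nut, v in draws.items()
        }
        groups.append(
            FoodGroup(
                group_id=gid,
                name=arch.name,
                serving_size_g=arch.serving_size_g,
                profile=NutrientProfile(
                    cho_g=per_serving[Nutrient.CHO],
                    ptn_g=per_serving[Nutrient.PTN],
                    fat_g=per_serving[Nutrient.FAT],
                ),
                weekly_unit_g=arch.weekly_unit_g,
            )
        )
    return FoodTable(groups), items


def generate_participants(
    spec: FixtureSpec,
) -> list[tuple[Participant, ActivityLevel]]:
    """Generate a roster spanning the anthropometry ranges.

    The first two participants anchor the extremes (smallest/oldest
    female, largest/youngest male), so after the default 1.6 activity
    factor the roster's EERs bracket the 5000-10,000 kJ comparison range
    whenever the default ranges are used; the rest are uniform draws.
    """
    rng = np.random.default_rng(spec.seed + 1)
    alo, ahi = spec.age_range_y
    hlo, hhi = spec.height_range_cm
    wlo, whi = spec.weight_range_kg
    roster: list[tuple[Participant, ActivityLevel]] = []
    # anchor sexes respect an all-female or all-male roster request
    low_sex = Sex.FEMALE if spec.female_fraction > 0 else Sex.MALE
    high_sex = Sex.MALE if spec.female_fraction < 1 else Sex.FEMALE
    anchors = [
        Participant(
            participant_id="p0001",
            sex=low_sex,
            age_y=ahi,
            height_cm=hlo,
            weight_kg=wlo,
        ),
        Participant(
            participant_id="p0002",
            sex=high_sex,
            age_y=alo,
            height_cm=hhi,
            weight_kg=whi,
        ),
    ]
    for p in anchors[: spec.n_participants]:
        roster.append((p, DEFAULT_ACTIVITY))
    for k in range(len(roster), spec.n_participants):
        sex = Sex.FEMALE if rng.random() < spec.female_fraction else Sex.MALE
        roster.append(
            (
                Participant(
                    participant_id=f"p{k + 1:04d}",
                    sex=sex,
                    age_y=float(np.round(rng.uniform(alo, ahi), 1)),
                    height_cm=float(np.round(rng.uniform(hlo, hhi), 1)),
                    weight_kg=float(np.round(rng.uniform(wlo, whi), 1)),
                ),
                DEFAULT_ACTIVITY,
            )
        )
    return roster


def random_instance(
    rng: np.random.Generator,
    n_groups: Optional[int] = None,
    max_groups: int = 6,
    small_energy: bool = False,
) -> tuple[StudyConfig, FoodTable, float]:
    """One randomized solve instance: config, table and a feasible energy cap.

    Groups get per-serving profiles with at least ~50 kJ each, grid-aligned
    serving minima, an occasional upper bound, and a random valid target
    split; the cap leaves headroom above the minima so the instance is
    feasible by construction. ``small_energy`` keeps the cap below ~4.5 MJ
    so the grid-enumeration oracle stays cheap.
    """
    if n_groups is None:
        n_groups = int(rng.integers(3, max_groups + 1))
    groups = []
    energy_floor = 150.0 if small_energy else 50.0  # keeps oracle grids small
    for k in range(n_groups):
        while True:
            cho = float(np.round(rng.uniform(0, 20), 2))
            ptn = float(np.round(rng.uniform(0, 12), 2))
            fat = float(np.round(rng.uniform(0, 8), 2))
            if 17 * cho + 17 * ptn + 36 * fat >= energy_floor:
                break
        groups.append(
            FoodGroup(
                group_id=f"g{k}",
                name=f"Random group {k}",
                serving_size_g=float(rng.integers(20, 200)),
                profile=NutrientProfile(cho_g=cho, ptn_g=ptn, fat_g=fat),
            )
        )
    table = FoodTable(groups)
    constraints = []
    for g in groups:
        lo = float(rng.integers(0, 5)) * 0.5  # on the half-serving grid
        hi = None
        if not small_energy and rng.random() < 0.25:
            hi = lo + float(rng.integers(2, 10))
        constraints.append(
            ServingConstraint(group_id=g.group_id, min_servings=lo, max_servings=hi)
        )
    cho_t = float(np.round(rng.uniform(35, 60), 1))
    ptn_t = float(np.round(rng.uniform(15, 30), 1))
    fat_t = float(np.round(100 - cho_t - ptn_t, 1))
    cfg = StudyConfig(
        study_id="random_instance",
        targets=MacroTargets(
            target_cho_pct=cho_t, target_ptn_pct=ptn_t, target_fat_pct=fat_t
        ),
        constraints=tuple(constraints),
    )
    minima_energy = sum(
        c.min_servings * table[c.group_id].energy_kj_per_serving for c in constraints
    )
    if small_energy:
        eer = minima_energy + float(rng.uniform(500, 1500))
    else:
        eer = max(minima_energy * float(rng.uniform(1.3, 2.5)), minima_energy + 500)
    return cfg, table, eer


# ---------------------------------------------------------------------------
# the exactly solvable instance
#
# Three groups each carrying a single macronutrient: 10 g carbohydrate,
# 10 g protein or 5 g fat per serving. For targets 50/20/30 and an energy
# cap E the zero-distance diet at the cap is
#   X_cho = 0.50 E / (17*10),  X_ptn = 0.20 E / (17*10),
#   X_fat = 0.30 E / (36*5),
# i.e. (10, 4, 5.6667) servings at E = 3400 kJ.

PURE_MACRO_EER_KJ = 3400.0
PURE_MACRO_OPTIMUM = {"cho_pure": 10.0, "ptn_pure": 4.0, "fat_pure": 17.0 / 3.0}


def pure_macro_table() -> FoodTable:
    """Deterministic table of three single-macronutrient groups."""
    return FoodTable(
        [
            FoodGroup(
                group_id="cho_pure",
                name="Pure carbohydrate",
                serving_size_g=50,
                profile=NutrientProfile(cho_g=10, ptn_g=0, fat_g=0),
            ),
            FoodGroup(
                group_id="ptn_pure",
                name="Pure protein",
                serving_size_g=50,
                profile=NutrientProfile(cho_g=0, ptn_g=10, fat_g=0),
            ),
            FoodGroup(
                group_id="fat_pure",
                name="Pure fat",
                serving_size_g=10,
                profile=NutrientProfile(cho_g=0, ptn_g=0, fat_g=5),
            ),
        ]
    )


def pure_macro_config() -> StudyConfig:
    """Unconstrained-minima study config for the pure-macronutrient table."""
    return StudyConfig(
        study_id="pure_macro",
        targets=MacroTargets(
            target_cho_pct=50.0, target_ptn_pct=20.0, target_fat_pct=30.0
        ),
        constraints=tuple(
            ServingConstraint(group_id=g) for g in ("cho_pure", "ptn_pure", "fat_pure")
        ),
    )


def write_fixture(spec: FixtureSpec, outdir: str | Path, preset: str = "realistic") -> dict[str, Path]:
    """Write a complete fixture set (foods, items, participants, study config).

    ``preset`` selects the food table: "realistic" generates the archetype
    roster from the spec; "exact" writes the pure-macronutrient table with
    its matching config. Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "foods": outdir / "foods.csv",
        "items": outdir / "items.csv",
        "participants": outdir / "participants.csv",
        "study": outdir / "study.yaml",
    }
    if preset == "exact":
        write_food_table(pure_macro_table(), paths["foods"])
        paths.pop("items")
        save_study_config(pure_macro_config(), paths["study"])
    elif preset == "realistic":
        table, items = generate_food_table(spec)
        write_food_table(table, paths["foods"])
        write_food_items(items, paths["items"])
        save_study_config(table1_default(), paths["study"])
    else:
        raise ValidationFailure(f"unknown preset {preset!r} (use 'exact' or 'realistic')")
    write_participants(generate_participants(spec), paths["participants"])
    return paths
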