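"""Food composition data model, CSV I/O, and group-level nutrient statistics.

A *food group* is the unit of prescription: an aggregated category
(vegetables, whole grains, ...) with a representative per-serving
macronutrient profile. Individual *food items* carry per-100 g profiles and
are used to build and screen the groupings: for each group we compute the
mean, SD, range and coefficient of variation (CV = SD/mean x 100) of each
macronutrient across member items, and flag groups whose CV is >= 15 % as
too heterogeneous to be represented by a single profile.
"""

from __future__ import annotations

import enum
import math
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Nutrient",
    "NutrientProfile",
    "FoodGroup",
    "FoodItem",
    "FoodTable",
    "GroupStatistics",
    "VariationFlag",
    "RankedSources",
    "FoodDataError",
    "SchemaError",
    "ValidationFailure",
    "load_food_table",
    "write_food_table",
    "load_food_items",
    "write_food_items",
    "group_statistics",
    "statistics_by_group",
    "flag_high_variation",
    "rank_primary_sources",
    "CHO_KJ_PER_G",
    "PTN_KJ_PER_G",
    "FAT_KJ_PER_G",
]

# Metabolizable energy factors, kJ per gram. No alcohol or fibre terms.
CHO_KJ_PER_G = 17.0
PTN_KJ_PER_G = 17.0
FAT_KJ_PER_G = 36.0

#: tolerance for the fatty-acid subclass closure check (grams)
_FAT_SUBCLASS_TOL = 1e-6


class FoodDataError(Exception):
    """Base class for food-table problems."""


class SchemaError(FoodDataError):
    """A required column is missing or the file is structurally unusable."""


class ValidationFailure(FoodDataError):
    """A row or value violates an invariant (negative grams, duplicate id, ...)."""


class Nutrient(str, enum.Enum):
    """Selector for a nutrient axis of a profile."""

    CHO = "cho"
    PTN = "ptn"
    FAT = "fat"
    SAT = "sat"
    MUFA = "mufa"
    PUFA = "pufa"


class NutrientProfile(BaseModel):
    """Macronutrient grams per serving (or per 100 g for item-level data).

    Fatty-acid subclasses are optional; when all three are present their sum
    may not exceed total fat (up to a small numerical tolerance).
    """

    model_config = ConfigDict(frozen=True)

    cho_g: float = Field(ge=0)
    ptn_g: float = Field(ge=0)
    fat_g: float = Field(ge=0)
    sat_g: Optional[float] = Field(default=None, ge=0)
    mufa_g: Optional[float] = Field(default=None, ge=0)
    pufa_g: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _subclasses_bounded_by_fat(self) -> "NutrientProfile":
        parts = [self.sat_g, self.mufa_g, self.pufa_g]
        if all(p is not None for p in parts):
            if sum(parts) > self.fat_g + _FAT_SUBCLASS_TOL:
                raise ValueError(
                    f"fatty-acid subclasses sum to {sum(parts):g} g "
                    f"> total fat {self.fat_g:g} g"
                )
        return self

    def get(self, nutrient: Nutrient | str) -> Optional[float]:
        """Value for a nutrient selector; None for an absent subclass."""
        nutrient = Nutrient(nutrient)
        return getattr(self, f"{nutrient.value}_g")

    @property
    def energy_kj(self) -> float:
        """Energy of this profile at 17/17/36 kJ per gram."""
        return (
            CHO_KJ_PER_G * self.cho_g
            + PTN_KJ_PER_G * self.ptn_g
            + FAT_KJ_PER_G * self.fat_g
        )

    def scaled(self, factor: float) -> "NutrientProfile":
        """Profile with every present field multiplied by ``factor``."""
        vals = {
            k: (v * factor if v is not None else None)
            for k, v in self.model_dump().items()
        }
        return NutrientProfile(**vals)


class FoodGroup(BaseModel):
    """A prescribable food group with a fixed serving mass.

    ``serving_size_g`` is the grams per counted serving (e.g. 30 g lean
    meat). ``weekly_unit_g`` optionally records the grams of a *practical*
    portion for groups advised per week (e.g. a 90 g fish portion counted in
    30 g serving units).
    """

    model_config = ConfigDict(frozen=True)

    group_id: str
    name: str
    serving_size_g: float = Field(gt=0)
    profile: NutrientProfile
    weekly_unit_g: Optional[float] = Field(default=None, gt=0)

    @property
    def energy_kj_per_serving(self) -> float:
        return self.profile.energy_kj


class FoodItem(BaseModel):
    """An individual food belonging to a group, profiled per 100 g."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    group_id: str
    profile_per_100g: NutrientProfile


class FoodTable:
    """An ordered collection of food groups with unique ids."""

    def __init__(self, groups: Iterable[FoodGroup]):
        self._groups: dict[str, FoodGroup] = {}
        for g in groups:
            if g.group_id in self._groups:
                raise ValidationFailure(f"duplicate group_id {g.group_id!r}")
            self._groups[g.group_id] = g

    def __iter__(self) -> Iterator[FoodGroup]:
        return iter(self._groups.values())

    def __len__(self) -> int:
        return len(self._groups)

    def __contains__(self, group_id: str) -> bool:
        return group_id in self._groups

    def __getitem__(self, group_id: str) -> FoodGroup:
        try:
            return self._groups[group_id]
        except KeyError:
            raise KeyError(f"unknown food group {group_id!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodTable):
            return NotImplemented
        return list(self) == list(other)

    @property
    def group_ids(self) -> list[str]:
        return list(self._groups)


_REQUIRED_COLS = ["group_id", "name", "serving_size_g", "cho_g", "ptn_g", "fat_g"]
_OPTIONAL_COLS = ["sat_g", "mufa_g", "pufa_g", "weekly_unit_g"]

_ITEM_REQUIRED_COLS = ["item_id", "group_id", "cho_g_100g", "ptn_g_100g", "fat_g_100g"]
_ITEM_OPTIONAL_COLS = ["sat_g_100g", "mufa_g_100g", "pufa_g_100g"]


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def load_food_table(path: str | Path) -> FoodTable:
    """Read a food-group table from CSV.

    Expected header: ``group_id,name,serving_size_g,cho_g,ptn_g,fat_g``
    with optional ``sat_g,mufa_g,pufa_g,weekly_unit_g``. Nutrient columns
    are grams per serving.

    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationFailure` (with the offending row number) for invalid
    values.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"food table not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"group_id": str, "name": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected a header row") from None
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")

    groups: list[FoodGroup] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # header is line 1
        try:
            profile = NutrientProfile(
                cho_g=row["cho_g"],
                ptn_g=row["ptn_g"],
                fat_g=row["fat_g"],
                sat_g=_opt(row.get("sat_g")),
                mufa_g=_opt(row.get("mufa_g")),
                pufa_g=_opt(row.get("pufa_g")),
            )
            groups.append(
                FoodGroup(
                    group_id=row["group_id"],
                    name=row["name"],
                    serving_size_g=row["serving_size_g"],
                    profile=profile,
                    weekly_unit_g=_opt(row.get("weekly_unit_g")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationFailure(f"{path} line {rowno}: {exc}") from None
    try:
        return FoodTable(groups)
    except ValidationFailure as exc:
        raise ValidationFailure(f"{path}: {exc}") from None


def write_food_table(table: FoodTable, path: str | Path) -> None:
    """Write a food-group table as CSV (inverse of :func:`load_food_table`)."""
    rows = []
    for g in table:
        p = g.profile
        rows.append(
            {
                "group_id": g.group_id,
                "name": g.name,
                "serving_size_g": g.serving_size_g,
                "cho_g": p.cho_g,
                "ptn_g": p.ptn_g,
                "fat_g": p.fat_g,
                "sat_g": p.sat_g,
                "mufa_g": p.mufa_g,
                "pufa_g": p.pufa_g,
                "weekly_unit_g": g.weekly_unit_g,
            }
        )
    df = pd.DataFrame(rows, columns=_REQUIRED_COLS + _OPTIONAL_COLS)
    # drop optional columns that are entirely absent so round-trips are exact
    for col in _OPTIONAL_COLS:
        if df[col].isna().all():
            df = df.drop(columns=[col])
    df.to_csv(path, index=False, float_format="%.6g")


def load_food_items(path: str | Path, table: FoodTable | None = None) -> list[FoodItem]:
    """Read item-level per-100 g profiles.

    Header: ``item_id,group_id,cho_g_100g,ptn_g_100g,fat_g_100g`` plus
    optional subclass columns. When ``table`` is given, every item's
    ``group_id`` must resolve against it.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"item table not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"item_id": str, "group_id": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected a header row") from None
    missing = [c for c in _ITEM_REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    items: list[FoodItem] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2
        try:
            profile = NutrientProfile(
                cho_g=row["cho_g_100g"],
                ptn_g=row["ptn_g_100g"],
                fat_g=row["fat_g_100g"],
                sat_g=_opt(row.get("sat_g_100g")),
                mufa_g=_opt(row.get("mufa_g_100g")),
                pufa_g=_opt(row.get("pufa_g_100g")),
            )
            item = FoodItem(
                item_id=row["item_id"],
                group_id=row["group_id"],
                profile_per_100g=profile,
            )
        except (ValueError, TypeError) as exc:
            raise ValidationFailure(f"{path} line {rowno}: {exc}") from None
        if table is not None and item.group_id not in table:
            raise ValidationFailure(
                f"{path} line {rowno}: unknown group_id {item.group_id!r}"
            )
        items.append(item)
    return items


def write_food_items(items: Sequence[FoodItem], path: str | Path) -> None:
    rows = []
    for it in items:
        p = it.profile_per_100g
        rows.append(
            {
                "item_id": it.item_id,
                "group_id": it.group_id,
                "cho_g_100g": p.cho_g,
                "ptn_g_100g": p.ptn_g,
                "fat_g_100g": p.fat_g,
                "sat_g_100g": p.sat_g,
                "mufa_g_100g": p.mufa_g,
                "pufa_g_100g": p.pufa_g,
            }
        )
    df = pd.DataFrame(rows, columns=_ITEM_REQUIRED_COLS + _ITEM_OPTIONAL_COLS)
    for col in _ITEM_OPTIONAL_COLS:
        if df[col].isna().all():
            df = df.drop(columns=[col])
    df.to_csv(path, index=False, float_format="%.6g")


def per_serving_profile(item: FoodItem, group: FoodGroup) -> NutrientProfile:
    """Convert an item's per-100 g profile to the group's serving mass."""
    return item.profile_per_100g.scaled(group.serving_size_g / 100.0)


class GroupStatistics(BaseModel):
    """Dispersion summary of one nutrient across the items of one group.

    ``cv`` is SD/mean x 100 (percent); it is undefined (``cv_defined`` is
    False) when the mean is zero. SD uses the sample (n-1) denominator,
    treating the group's items as a sample of the wider food supply; a
    single-item group has SD = 0 by convention.
    """

    model_config = ConfigDict(frozen=True)

    group_id: str
    nutrient: Nutrient
    n_items: int = Field(ge=1)
    mean: float
    sd: float = Field(ge=0)
    value_range: float = Field(ge=0)
    cv: Optional[float] = None
    cv_defined: bool = True


class VariationFlag(str, enum.Enum):
    """Outcome of the within-group homogeneity screen."""

    ACCEPTABLE = "acceptable"
    EXCESSIVE = "excessive"
    NEEDS_MANUAL_COMPARISON = "needs_manual_comparison"


def group_statistics(
    items: Sequence[FoodItem], nutrient: Nutrient | str
) -> GroupStatistics:
    """Mean, sample SD, range and CV of one nutrient across a group's items.

    All items must belong to the same group and carry the selected nutrient.
    """
    nutrient = Nutrient(nutrient)
    if len(items) == 0:
        raise ValidationFailure("group_statistics requires at least one item")
    gids = {it.group_id for it in items}
    if len(gids) > 1:
        raise ValidationFailure(
            f"items span several groups ({', '.join(sorted(gids))}); "
            "call statistics_by_group instead"
        )
    raw = [it.profile_per_100g.get(nutrient) for it in items]
    if any(v is None for v in raw):
        raise ValidationFailure(
            f"nutrient {nutrient.value!r} absent for some items in group {gids.pop()!r}"
        )
    values = np.asarray(raw, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    value_range = float(values.max() - values.min())
    if mean > 0:
        cv, cv_defined = sd / mean * 100.0, True
    else:
        cv, cv_defined = None, False
    return GroupStatistics(
        group_id=items[0].group_id,
        nutrient=nutrient,
        n_items=len(items),
        mean=mean,
        sd=sd,
        value_range=value_range,
        cv=cv,
        cv_defined=cv_defined,
    )


def statistics_by_group(
    items: Sequence[FoodItem], nutrient: Nutrient | str
) -> dict[str, GroupStatistics]:
    """Per-group :func:`group_statistics`, keyed by group id."""
    by_group: dict[str, list[FoodItem]] = {}
    for it in items:
        by_group.setdefault(it.group_id, []).append(it)
    return {
        gid: group_statistics(members, nutrient)
        for gid, members in by_group.items()
    }


def flag_high_variation(
    stats: GroupStatistics, threshold: float = 15.0
) -> VariationFlag:
    """Screen a group's CV against the homogeneity threshold.

    Acceptable iff CV < threshold (strictly): a CV of exactly 15 % fails.
    A zero-mean nutrient has no CV and is referred to manual comparison
    against published exchange lists.
    """
    if not stats.cv_defined:
        return VariationFlag.NEEDS_MANUAL_COMPARISON
    return (
        VariationFlag.ACCEPTABLE
        if stats.cv < threshold
        else VariationFlag.EXCESSIVE
    )


class RankedSources(BaseModel):
    """Primary food-group sources of a nutrient.

    ``primary_groups`` is the longest descending-contribution prefix whose
    cumulative share stays strictly below the cutoff; ``shares`` and
    ``cumulative`` cover all groups in rank order.
    """

    model_config = ConfigDict(frozen=True)

    nutrient: Nutrient
    ranked_groups: list[str]
    shares: list[float]
    cumulative: list[float]
    primary_groups: list[str]
    warning: Optional[str] = None


def rank_primary_sources(
    items: Sequence[FoodItem],
    nutrient: Nutrient | str,
    cutoff: float = 0.75,
) -> RankedSources:
    """Rank groups by contribution to a nutrient and take the top sources.

    Groups are ordered by descending share of the total nutrient mass
    across all items; the *primary* sources are the longest prefix whose
    cumulative share is < ``cutoff`` (default 75 %). Degenerate inputs
    (single dominant group at or above the cutoff) yield an empty prefix
    with a warning rather than an error.
    """
    nutrient = Nutrient(nutrient)
    totals: dict[str, float] = {}
    for it in items:
        v = it.profile_per_100g.get(nutrient)
        totals[it.group_id] = totals.get(it.group_id, 0.0) + (v or 0.0)
    grand = sum(totals.values())
    if grand <= 0:
        raise ValidationFailure(
            f"all contributions to {nutrient.value!r} are zero; nothing to rank"
        )
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    gids = [gid for gid, _ in ranked]
    shares = [v / grand for _, v in ranked]
    cumulative = list(np.cumsum(shares))
    prefix: list[str] = []
    for gid, cum in zip(gids, cumulative):
        if cum < cutoff:
            prefix.append(gid)
        else:
            break
    warning = None
    if not prefix:
        warning = (
            f"top group {gids[0]!r} alone reaches {cumulative[0]:.0%} "
            f">= cutoff {cutoff:.0%}; no strict-prefix primary sources"
        )
    return RankedSources(
        nutrient=nutrient,
        ranked_groups=gids,
        shares=shares,
        cumulative=[float(c) for c in cumulative],
        primary_groups=prefix,
        warning=warning,
    )
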