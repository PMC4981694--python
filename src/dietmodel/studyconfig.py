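"""Trial-level macronutrient targets and per-group serving constraints.

A study configuration holds the trial's macronutrient energy split
(e.g. 50 % carbohydrate / 20 % protein / 30 % fat) and a constraint per
food group: a minimum daily serving target T_i, an optional maximum, and
the serving granularity used for rounded output. Per-participant overrides
(e.g. swapping lean meat for meat alternatives in a vegetarian diet) are
pure transformations, so the trial defaults are untouched for the next
participant.

Configs serialize to a small YAML document with ``targets:`` and
``constraints:`` sections; the bundled ``table1_default`` config encodes
the Excel-Solver constraint set used for the validation models, including
its high-energy variant (for models of 8500 kJ and above the lean-meat
minimum rises to 5 servings and the sugar cap is lifted).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .foodspec import ValidationFailure

__all__ = [
    "MacroTargets",
    "ServingConstraint",
    "StudyConfig",
    "ParticipantOverride",
    "load_study_config",
    "save_study_config",
    "table1_default",
    "apply_override",
    "high_energy_adjustment",
    "HIGH_ENERGY_THRESHOLD_KJ",
]

#: lower edge (inclusive) of the high-energy model band
HIGH_ENERGY_THRESHOLD_KJ = 8500.0

_TARGET_SUM_TOL = 0.01


class MacroTargets(BaseModel):
    """Target percentages of total energy from carbohydrate/protein/fat."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    target_cho_pct: float = Field(gt=0, lt=100)
    target_ptn_pct: float = Field(gt=0, lt=100)
    target_fat_pct: float = Field(gt=0, lt=100)

    @model_validator(mode="after")
    def _sums_to_100(self) -> "MacroTargets":
        total = self.target_cho_pct + self.target_ptn_pct + self.target_fat_pct
        if not math.isclose(total, 100.0, abs_tol=_TARGET_SUM_TOL):
            raise ValueError(f"macronutrient targets sum to {total:g}, expected 100")
        return self

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.target_cho_pct, self.target_ptn_pct, self.target_fat_pct)


class ServingConstraint(BaseModel):
    """Serving bounds for one food group.

    ``min_servings`` is the trial's daily target T_i (the solver's lower
    bound). ``max_servings`` is optional; with ``max_exclusive`` the bound
    is strict and the solver uses ``max_servings - increment``.
    ``increment`` is the grid for rounded output (default half servings);
    ``integral`` requests whole-serving rounding for this group.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    group_id: str
    min_servings: float = Field(default=0.0, ge=0)
    max_servings: Optional[float] = None
    max_exclusive: bool = False
    increment: float = Field(default=0.5, gt=0)
    integral: bool = False

    @model_validator(mode="after")
    def _bounds_ordered(self) -> "ServingConstraint":
        if self.max_servings is not None and self.max_servings < self.min_servings:
            raise ValueError(
                f"{self.group_id}: max_servings {self.max_servings:g} "
                f"< min_servings {self.min_servings:g}"
            )
        return self

    @property
    def effective_max(self) -> Optional[float]:
        """Upper bound as consumed by the solver (strict max backed off one increment)."""
        if self.max_servings is None:
            return None
        if self.max_exclusive:
            return self.max_servings - self.increment
        return self.max_servings

    @property
    def rounding_increment(self) -> float:
        return 1.0 if self.integral else self.increment


class StudyConfig(BaseModel):
    """Trial targets plus the per-group constraint set."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    study_id: str
    targets: MacroTargets
    constraints: tuple[ServingConstraint, ...]
    energy_rule: str = "at_most_eer"

    @model_validator(mode="after")
    def _unique_groups(self) -> "StudyConfig":
        seen: set[str] = set()
        for c in self.constraints:
            if c.group_id in seen:
                raise ValueError(f"duplicate constraint for group {c.group_id!r}")
            seen.add(c.group_id)
        if self.energy_rule != "at_most_eer":
            raise ValueError(f"unsupported energy_rule {self.energy_rule!r}")
        return self

    def constraint_for(self, group_id: str) -> Optional[ServingConstraint]:
        for c in self.constraints:
            if c.group_id == group_id:
                return c
        return None

    @property
    def group_ids(self) -> list[str]:
        return [c.group_id for c in self.constraints]


class ParticipantOverride(BaseModel):
    """Per-participant amendment: drop groups and/or replace constraints."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    removed_groups: tuple[str, ...] = ()
    added_or_replaced_constraints: tuple[ServingConstraint, ...] = ()

    @model_validator(mode="after")
    def _no_overlap(self) -> "ParticipantOverride":
        removed = set(self.removed_groups)
        added = {c.group_id for c in self.added_or_replaced_constraints}
        clash = removed & added
        if clash:
            raise ValueError(
                f"group(s) both removed and (re)added: {', '.join(sorted(clash))}"
            )
        return self


def table1_default() -> StudyConfig:
    """The bundled default constraint set (50/20/30 split).

    Minima/maxima per group: vegetables >= 5, whole grains >= 4, fruits in
    [2, 4), sugar <= 3, low-fat milk/yoghurt >= 2.5, whole milk and whole
    soy milk excluded, lean meat (30 g servings) >= 3, cheese / eggs /
    spreads free, oily fish >= 0.43 servings/day (one 90 g portion per
    week counted in 30 g units).
    """
    c = ServingConstraint
    return StudyConfig(
        study_id="table1_default",
        targets=MacroTargets(
            target_cho_pct=50.0, target_ptn_pct=20.0, target_fat_pct=30.0
        ),
        constraints=(
            c(group_id="vegetables", min_servings=5),
            c(group_id="whole_grains", min_servings=4),
            c(group_id="fruits", min_servings=2, max_servings=4, max_exclusive=True),
            c(group_id="sugar", max_servings=3),
            c(group_id="milk_yoghurt_low_fat", min_servings=2.5),
            c(group_id="milk_yoghurt_whole", max_servings=0),
            c(group_id="soy_milk_whole", max_servings=0),
            c(group_id="lean_meat", min_servings=3),
            c(group_id="cheese"),
            c(group_id="eggs"),
            c(group_id="oily_fish", min_servings=0.43),
            c(group_id="mufa"),
            c(group_id="pufa"),
        ),
    )


def _config_to_dict(cfg: StudyConfig) -> dict:
    doc: dict = {
        "study_id": cfg.study_id,
        "energy_rule": cfg.energy_rule,
        "targets": {
            "cho_pct": cfg.targets.target_cho_pct,
            "ptn_pct": cfg.targets.target_ptn_pct,
            "fat_pct": cfg.targets.target_fat_pct,
        },
        "constraints": [],
    }
    for c in cfg.constraints:
        row: dict = {"group_id": c.group_id}
        if c.min_servings:
            row["min_servings"] = c.min_servings
        if c.max_servings is not None:
            row["max_servings"] = c.max_servings
        if c.max_exclusive:
            row["max_exclusive"] = True
        if c.increment != 0.5:
            row["increment"] = c.increment
        if c.integral:
            row["integral"] = True
        doc["constraints"].append(row)
    return doc


def save_study_config(cfg: StudyConfig, path: str | Path) -> None:
    """Serialize a config to YAML; ``load_study_config`` inverts this."""
    Path(path).write_text(
        yaml.safe_dump(_config_to_dict(cfg), sort_keys=False), encoding="utf-8"
    )


def load_study_config(source: str | Path) -> StudyConfig:
    """Load a study config.

    ``source`` is either the name of a built-in config (``table1_default``)
    or a path to a YAML document with ``targets:`` and ``constraints:``
    sections. Unknown fields and targets not summing to 100 are rejected.
    """
    if str(source) == "table1_default":
        return table1_default()
    path = Path(source)
    if not path.exists():
        raise ValidationFailure(f"study config not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ValidationFailure(f"{path}: malformed YAML ({exc})") from None
    if not isinstance(doc, dict):
        raise ValidationFailure(f"{path}: expected a mapping at top level")
    try:
        targets_doc = doc.get("targets", {})
        known = {"cho_pct", "ptn_pct", "fat_pct"}
        unknown = set(targets_doc) - known
        if unknown:
            raise ValueError(f"unknown targets field(s): {', '.join(sorted(unknown))}")
        targets = MacroTargets(
            target_cho_pct=targets_doc.get("cho_pct"),
            target_ptn_pct=targets_doc.get("ptn_pct"),
            target_fat_pct=targets_doc.get("fat_pct"),
        )
        constraints = tuple(
            ServingConstraint(**row) for row in doc.get("constraints", [])
        )
        top_unknown = set(doc) - {"study_id", "energy_rule", "targets", "constraints"}
        if top_unknown:
            raise ValueError(f"unknown field(s): {', '.join(sorted(top_unknown))}")
        return StudyConfig(
            study_id=doc.get("study_id", path.stem),
            targets=targets,
            constraints=constraints,
            energy_rule=doc.get("energy_rule", "at_most_eer"),
        )
    except (ValueError, TypeError) as exc:
        raise ValidationFailure(f"{path}: {exc}") from None


def apply_override(cfg: StudyConfig, override: ParticipantOverride) -> StudyConfig:
    """Return a new config with a participant's amendments applied.

    Removal drops the group's constraint entirely (the group may still be
    excluded from the food table by the caller); added constraints replace
    any same-group entry. The input config is never mutated, so trial
    defaults are automatically restored for the next participant.
    """
    for gid in override.removed_groups:
        if cfg.constraint_for(gid) is None:
            raise ValidationFailure(
                f"override removes unknown group {gid!r} "
                f"(known: {', '.join(cfg.group_ids)})"
            )
    removed = set(override.removed_groups)
    replaced = {c.group_id: c for c in override.added_or_replaced_constraints}
    kept = [
        replaced.pop(c.group_id, c)
        for c in cfg.constraints
        if c.group_id not in removed
    ]
    new_constraints = tuple(kept) + tuple(replaced.values())
    return cfg.model_copy(update={"constraints": new_constraints})


def high_energy_adjustment(cfg: StudyConfig, eer_kj: float) -> StudyConfig:
    """Apply the high-energy constraint variant when EER >= 8500 kJ.

    For models in the 8500-10,000 kJ band the lean-meat minimum is raised
    to 5 servings/day and the sugar upper bound is removed. Below the
    (inclusive) threshold the config is returned unchanged.
    """
    if eer_kj <= 0:
        raise ValidationFailure(f"eer_kj must be positive, got {eer_kj:g}")
    if eer_kj < HIGH_ENERGY_THRESHOLD_KJ:
        return cfg
    new_constraints = []
    for c in cfg.constraints:
        if c.group_id == "lean_meat":
            c = c.model_copy(update={"min_servings": max(c.min_servings, 5.0)})
        elif c.group_id == "sugar":
            c = c.model_copy(update={"max_servings": None, "max_exclusive": False})
        new_constraints.append(c)
    return cfg.model_copy(update={"constraints": tuple(new_constraints)})
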