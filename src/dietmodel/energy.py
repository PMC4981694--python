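"""Resting energy expenditure and estimated energy requirement.

REE comes from the Mifflin-St Jeor equations on weight (kg), height (cm)
and age (years):

    female: REE = 9.99 w + 6.25 h - 4.92 a - 161   (kcal/day)
    male:   REE = 9.99 w + 6.25 h - 4.92 a + 5     (kcal/day)

EER = REE x PA, where PA is a standardized physical-activity factor
(default 1.6, light activity). The equations are calorie-denominated while
diet models are framed in kilojoules, so both units are carried using the
thermochemical conversion 1 kcal = 4.184 kJ; the solver consumes kJ.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .foodspec import SchemaError, ValidationFailure

__all__ = [
    "Sex",
    "Participant",
    "ActivityLevel",
    "EnergyRequirement",
    "ACTIVITY_LEVELS",
    "DEFAULT_ACTIVITY",
    "KJ_PER_KCAL",
    "resting_energy_expenditure",
    "estimated_energy_requirement",
    "load_participants",
    "write_participants",
]

KJ_PER_KCAL = 4.184


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Participant(BaseModel):
    """Anthropometry of one trial participant."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    sex: Sex
    age_y: float = Field(gt=0)
    height_cm: float = Field(gt=0)
    weight_kg: float = Field(gt=0)


class ActivityLevel(BaseModel):
    """A named physical-activity multiplier (PA >= 1)."""

    model_config = ConfigDict(frozen=True)

    label: str
    pa_factor: float = Field(ge=1.0)


#: standard dietetic-practice activity menu; "light" (1.6) is the default
#: applied to every participant unless the roster says otherwise.
ACTIVITY_LEVELS: dict[str, ActivityLevel] = {
    "sedentary": ActivityLevel(label="sedentary", pa_factor=1.2),
    "light": ActivityLevel(label="light", pa_factor=1.6),
    "moderate": ActivityLevel(label="moderate", pa_factor=1.75),
    "very_active": ActivityLevel(label="very_active", pa_factor=1.9),
}
DEFAULT_ACTIVITY = ACTIVITY_LEVELS["light"]


class EnergyRequirement(BaseModel):
    """REE and EER in both kcal/day and kJ/day."""

    model_config = ConfigDict(frozen=True)

    ree_kcal: float
    ree_kj: float
    eer_kcal: float
    eer_kj: float
    pa_factor: float


def resting_energy_expenditure(p: Participant) -> float:
    """Mifflin-St Jeor REE in kcal/day (sex-specific intercept)."""
    base = 9.99 * p.weight_kg + 6.25 * p.height_cm - 4.92 * p.age_y
    return base - 161.0 if p.sex is Sex.FEMALE else base + 5.0


def estimated_energy_requirement(
    p: Participant, activity: ActivityLevel = DEFAULT_ACTIVITY
) -> EnergyRequirement:
    """EER = REE x PA, carried at full precision in kcal and kJ."""
    ree = resting_energy_expenditure(p)
    eer = ree * activity.pa_factor
    return EnergyRequirement(
        ree_kcal=ree,
        ree_kj=ree * KJ_PER_KCAL,
        eer_kcal=eer,
        eer_kj=eer * KJ_PER_KCAL,
        pa_factor=activity.pa_factor,
    )


_ROSTER_COLS = ["participant_id", "sex", "age_y", "height_cm", "weight_kg"]


def load_participants(
    path: str | Path,
) -> list[tuple[Participant, ActivityLevel]]:
    """Read a participant roster CSV.

    Header: ``participant_id,sex,age_y,height_cm,weight_kg`` with an
    optional ``activity_label`` column resolved against the standard menu
    (default "light").
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"participant roster not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"participant_id": str, "sex": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected a header row") from None
    missing = [c for c in _ROSTER_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    roster: list[tuple[Participant, ActivityLevel]] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2
        try:
            p = Participant(
                participant_id=row["participant_id"],
                sex=Sex(str(row["sex"]).strip().lower()),
                age_y=row["age_y"],
                height_cm=row["height_cm"],
                weight_kg=row["weight_kg"],
            )
        except ValueError as exc:
            raise ValidationFailure(f"{path} line {rowno}: {exc}") from None
        label: Optional[str] = None
        if "activity_label" in df.columns and pd.notna(row["activity_label"]):
            label = str(row["activity_label"]).strip()
        if label is None:
            activity = DEFAULT_ACTIVITY
        elif label in ACTIVITY_LEVELS:
            activity = ACTIVITY_LEVELS[label]
        else:
            raise ValidationFailure(
                f"{path} line {rowno}: unknown activity_label {label!r} "
                f"(known: {', '.join(ACTIVITY_LEVELS)})"
            )
        roster.append((p, activity))
    return roster


def write_participants(
    roster: list[tuple[Participant, ActivityLevel]], path: str | Path
) -> None:
    rows = [
        {
            "participant_id": p.participant_id,
            "sex": p.sex.value,
            "age_y": p.age_y,
            "height_cm": p.height_cm,
            "weight_kg": p.weight_kg,
            "activity_label": a.label,
        }
        for p, a in roster
    ]
    pd.DataFrame(rows, columns=_ROSTER_COLS + ["activity_label"]).to_csv(
        path, index=False, float_format="%.6g"
    )
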