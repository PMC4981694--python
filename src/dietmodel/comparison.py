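"""Method-vs-reference comparison arithmetic for diet models.

Validation of an automated modeling method is asymmetric: the manual model
built by an experienced dietitian is the reference, and each alternative
method's servings are scored by the absolute percent difference

    pct_diff = |method - reference| / reference x 100,

rounded to the nearest integer (half away from zero) for display. The
comparison grid spans one row per (method, energy target, food group),
with energy targets conventionally running 5000-10,000 kJ in 500-kJ steps.

Also provided: the daily-servings to weekly-portions conversion used for
infrequent groups (a fish prescription of 0.43 servings/day in 30 g units
is one 90 g portion per week).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .foodspec import SchemaError, ValidationFailure
from .optimizer import Prescription

__all__ = [
    "ComparisonRow",
    "percent_difference",
    "percent_difference_raw",
    "compare_models",
    "weekly_frequency",
    "load_method_prescriptions",
    "write_comparison",
]


class ComparisonRow(BaseModel):
    """One cell of a method-vs-reference table."""

    model_config = ConfigDict(frozen=True)

    model_label: str
    energy_target_kj: float
    group_id: str
    servings: float = Field(ge=0)
    reference_servings: Optional[float] = None
    pct_diff: Optional[int] = None
    pct_diff_raw: Optional[float] = None
    warning: Optional[str] = None


def percent_difference_raw(x: float, ref: float) -> float:
    """Unrounded |x - ref| / ref x 100. ``ref`` must be positive."""
    if ref <= 0:
        raise ValidationFailure(
            f"percent difference undefined for reference {ref:g} (must be > 0)"
        )
    return abs(x - ref) / ref * 100.0


def percent_difference(x: float, ref: float) -> int:
    """Integer percent difference, rounded half away from zero.

    Display convention for comparison tables; feed unrounded servings when
    available, since rounding the inputs first can shift the cell by a
    point (0.286 vs 0.58 gives 51; pre-rounded 0.29 would give 50).
    """
    v = percent_difference_raw(x, ref)
    return int(math.floor(v + 0.5))


def weekly_frequency(
    servings_per_day: float, unit_g: float, portion_g: float
) -> float:
    """Convert daily servings in counting units to practical portions/week.

    ``unit_g`` is the grams of one counted serving unit (e.g. 30 g fish);
    ``portion_g`` the grams of one practical portion (e.g. a 90 g fillet).
    """
    if unit_g <= 0 or portion_g <= 0:
        raise ValidationFailure("unit_g and portion_g must be positive")
    if servings_per_day < 0:
        raise ValidationFailure("servings_per_day must be >= 0")
    return servings_per_day * 7.0 * unit_g / portion_g


def compare_models(
    methods: Mapping[str, Mapping[float, Prescription]],
    reference: Mapping[float, Prescription],
) -> list[ComparisonRow]:
    """Score each method's prescriptions against the reference method.

    ``methods`` maps a method label to {energy target kJ -> prescription};
    ``reference`` maps energy targets to the reference prescriptions. One
    row is emitted per (method, energy target, group) over the method's own
    group vocabulary; groups missing from the reference produce a row with
    an undefined percent difference and a warning, as does a zero reference
    serving.
    """
    rows: list[ComparisonRow] = []
    for label in methods:
        for kj in sorted(methods[label]):
            pres = methods[label][kj]
            ref_pres = reference.get(kj)
            for gid, servings in pres.servings.items():
                ref_val: Optional[float] = None
                warning: Optional[str] = None
                if ref_pres is None:
                    warning = f"no reference model for the {kj:g} kJ target"
                elif gid not in ref_pres.servings:
                    warning = f"group {gid!r} absent from the reference model"
                else:
                    ref_val = ref_pres.servings[gid]
                if ref_val is not None and ref_val > 0:
                    raw = percent_difference_raw(servings, ref_val)
                    rows.append(
                        ComparisonRow(
                            model_label=label,
                            energy_target_kj=kj,
                            group_id=gid,
                            servings=servings,
                            reference_servings=ref_val,
                            pct_diff=percent_difference(servings, ref_val),
                            pct_diff_raw=raw,
                        )
                    )
                else:
                    if ref_val is not None and warning is None:
                        warning = "reference prescribes zero servings"
                    rows.append(
                        ComparisonRow(
                            model_label=label,
                            energy_target_kj=kj,
                            group_id=gid,
                            servings=servings,
                            reference_servings=ref_val,
                            warning=warning,
                        )
                    )
    return rows


_METHOD_COLS = ["kj_target", "group_id", "servings"]


def load_method_prescriptions(path: str | Path) -> dict[float, Prescription]:
    """Read one method's prescriptions from CSV (``kj_target,group_id,servings``)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"prescription file not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"group_id": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected a header row") from None
    missing = [c for c in _METHOD_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    out: dict[float, dict[str, float]] = {}
    for idx, row in df.iterrows():
        kj = float(row["kj_target"])
        s = float(row["servings"])
        if s < 0:
            raise ValidationFailure(
                f"{path} line {int(idx) + 2}: negative servings {s:g}"
            )
        out.setdefault(kj, {})[str(row["group_id"])] = s
    return {kj: Prescription(servings=sv) for kj, sv in out.items()}


def write_comparison(rows: Sequence[ComparisonRow], path: str | Path) -> None:
    """Write comparison rows as CSV (``model,kj_target,group,servings,pct_diff``)."""
    df = pd.DataFrame(
        [
            {
                "model": r.model_label,
                "kj_target": r.energy_target_kj,
                "group": r.group_id,
                "servings": r.servings,
                "reference_servings": r.reference_servings,
                "pct_diff": r.pct_diff,
                "warning": r.warning,
            }
            for r in rows
        ],
        columns=[
            "model",
            "kj_target",
            "group",
            "servings",
            "reference_servings",
            "pct_diff",
            "warning",
        ],
    )
    df.to_csv(path, index=False, float_format="%.6g")
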