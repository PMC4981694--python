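"""Constrained nonlinear solve for individualized serving prescriptions.

The decision vector X assigns daily servings to each food group. Diet
totals follow from the per-serving profiles:

    TotalCHO = sum_i X_i * cho_i     (grams; likewise protein and fat)
    TotalEnergy = 17*TotalCHO + 17*TotalPTN + 36*TotalFAT   (kJ)

and each macronutrient's share of energy is its own energy contribution
over the total (%CHO = 17*TotalCHO/TotalEnergy x 100, etc.), so the three
percentages always close to 100. The objective is the Euclidean distance

    d = sqrt((%CHO - TargetCHO)^2 + (%PTN - TargetPTN)^2 + (%FAT - TargetFAT)^2)

minimized subject to X_i >= T_i (and any configured maxima) and
TotalEnergy <= EER.

The printed problem alone does not pin down a unique answer: percentages
are scale-invariant, so any zero-distance diet stays optimal when shrunk.
A lexicographic secondary objective resolves this: among minimal-distance
diets the solver maximizes total energy, so prescriptions approach the
participant's requirement from below rather than undershooting it.

The solve itself is multi-start SLSQP (sequential quadratic programming)
on the squared distance with an analytic gradient, started from the
serving minima, from an energy-scaled feasible point, and from seeded
random feasible points. A grid-enumeration oracle (`brute_force_solve`)
is provided for small instances.
"""

from __future__ import annotations

import enum
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.optimize import NonlinearConstraint, minimize

from .foodspec import (
    CHO_KJ_PER_G,
    FAT_KJ_PER_G,
    PTN_KJ_PER_G,
    FoodTable,
    ValidationFailure,
)
from .studyconfig import MacroTargets, StudyConfig

__all__ = [
    "Prescription",
    "DietTotals",
    "SolveStatus",
    "SolveResult",
    "RoundingResult",
    "diet_totals",
    "macro_distance",
    "solve",
    "brute_force_solve",
    "round_prescription",
]

_ENERGY_FACTORS = np.array([CHO_KJ_PER_G, PTN_KJ_PER_G, FAT_KJ_PER_G])

#: convergence tolerance on the distance objective (percentage points)
DISTANCE_TOL = 1e-6
#: cap on multi-start restarts
MAX_RESTARTS = 50


class Prescription(BaseModel):
    """Daily servings per food group (the decision vector X)."""

    model_config = ConfigDict(frozen=True)

    servings: dict[str, float]

    @classmethod
    def of(cls, **servings: float) -> "Prescription":
        return cls(servings=servings)

    def __getitem__(self, group_id: str) -> float:
        return self.servings[group_id]


class DietTotals(BaseModel):
    """Grams, energy and macronutrient energy percentages of a prescription.

    Percentages are None (``defined`` False) for a zero-energy diet.
    """

    model_config = ConfigDict(frozen=True)

    total_cho_g: float = Field(ge=0)
    total_ptn_g: float = Field(ge=0)
    total_fat_g: float = Field(ge=0)
    total_energy_kj: float = Field(ge=0)
    pct_cho: Optional[float] = None
    pct_ptn: Optional[float] = None
    pct_fat: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.pct_cho is not None

    def percentages(self) -> tuple[float, float, float]:
        if not self.defined:
            raise ValidationFailure(
                "macronutrient percentages undefined for a zero-energy diet"
            )
        return (self.pct_cho, self.pct_ptn, self.pct_fat)


class SolveStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    NOT_CONVERGED = "not_converged"


class SolveResult(BaseModel):
    """Outcome of a solve: continuous optimum, rounded counterpart, totals."""

    model_config = ConfigDict(frozen=True)

    status: SolveStatus
    prescription: Optional[Prescription] = None
    totals: Optional[DietTotals] = None
    distance: Optional[float] = None
    rounded: Optional[Prescription] = None
    rounded_totals: Optional[DietTotals] = None
    rounded_distance: Optional[float] = None
    infeasibility_margin_kj: Optional[float] = None
    diagnostics: dict = Field(default_factory=dict)


class RoundingResult(BaseModel):
    """A prescription snapped to the serving grid, with the energy effect."""

    model_config = ConfigDict(frozen=True)

    prescription: Prescription
    energy_change_kj: float
    feasible: bool
    warning: Optional[str] = None


def _macro_matrix(table: FoodTable, group_ids: Sequence[str]) -> np.ndarray:
    """3 x n matrix of per-serving grams (CHO; PTN; FAT) for the given groups."""
    cols = []
    for gid in group_ids:
        p = table[gid].profile
        cols.append([p.cho_g, p.ptn_g, p.fat_g])
    return np.array(cols, dtype=float).T


def diet_totals(x: Prescription, table: FoodTable) -> DietTotals:
    """Grams, kJ and energy percentages for a prescription.

    Unknown groups raise; an all-zero prescription yields zero totals with
    undefined percentages rather than an error.
    """
    gids = list(x.servings)
    for gid in gids:
        table[gid]  # raises KeyError for unknown groups
    if not gids:
        return DietTotals(
            total_cho_g=0.0, total_ptn_g=0.0, total_fat_g=0.0, total_energy_kj=0.0
        )
    C = _macro_matrix(table, gids)
    xv = np.array([x.servings[g] for g in gids], dtype=float)
    if np.any(xv < 0):
        raise ValidationFailure("negative servings in prescription")
    grams = C @ xv
    energy_parts = _ENERGY_FACTORS * grams
    energy = float(energy_parts.sum())
    if energy <= 0:
        return DietTotals(
            total_cho_g=float(grams[0]),
            total_ptn_g=float(grams[1]),
            total_fat_g=float(grams[2]),
            total_energy_kj=0.0,
        )
    pct = energy_parts / energy * 100.0
    return DietTotals(
        total_cho_g=float(grams[0]),
        total_ptn_g=float(grams[1]),
        total_fat_g=float(grams[2]),
        total_energy_kj=energy,
        pct_cho=float(pct[0]),
        pct_ptn=float(pct[1]),
        pct_fat=float(pct[2]),
    )


def macro_distance(t: DietTotals, targets: MacroTargets) -> float:
    """Euclidean distance (percentage points) of achieved from target split."""
    achieved = np.array(t.percentages())
    target = np.array(targets.as_tuple())
    return float(np.linalg.norm(achieved - target))


class _Problem:
    """Vectorized arrays for one solve instance."""

    def __init__(self, cfg: StudyConfig, table: FoodTable, eer_kj: float):
        if eer_kj <= 0:
            raise ValidationFailure(f"eer_kj must be positive, got {eer_kj:g}")
        for c in cfg.constraints:
            if c.group_id not in table:
                raise ValidationFailure(
                    f"constraint references group {c.group_id!r} absent from the food table"
                )
        # decision variables: every group in the table, in table order
        self.group_ids = table.group_ids
        self.C = _macro_matrix(table, self.group_ids)  # 3 x n grams/serving
        self.e = _ENERGY_FACTORS @ self.C  # kJ/serving per group
        n = len(self.group_ids)
        lb = np.zeros(n)
        ub = np.full(n, np.inf)
        for i, gid in enumerate(self.group_ids):
            c = cfg.constraint_for(gid)
            if c is None:
                continue
            lb[i] = c.min_servings
            m = c.effective_max
            if m is not None:
                ub[i] = m
        if np.any(ub < lb):
            bad = [
                self.group_ids[i] for i in np.nonzero(ub < lb)[0]
            ]
            raise ValidationFailure(
                f"empty serving interval for group(s): {', '.join(bad)}"
            )
        self.lb, self.ub = lb, ub
        self.eer_kj = eer_kj
        self.targets = np.array(cfg.targets.as_tuple())

    def energy(self, x: np.ndarray) -> float:
        return float(self.e @ x)

    def sq_distance(self, x: np.ndarray) -> float:
        g = self.C @ x
        parts = _ENERGY_FACTORS * g
        E = parts.sum()
        if E <= 1e-12:
            return 1e6  # zero-energy corner: heavily penalized, off the feasible path
        r = parts / E * 100.0 - self.targets
        return float(r @ r)

    def sq_distance_grad(self, x: np.ndarray) -> np.ndarray:
        g = self.C @ x
        parts = _ENERGY_FACTORS * g
        E = parts.sum()
        if E <= 1e-12:
            return np.zeros_like(x)
        r = parts / E * 100.0 - self.targets
        # d pct_k / d x_i = 100 * f_k (C_ki E - g_k e_i) / E^2
        fC = _ENERGY_FACTORS[:, None] * self.C  # 3 x n energy per serving by macro
        J = 100.0 * (fC * E - parts[:, None] * self.e[None, :]) / E**2
        return 2.0 * (r @ J)

    def feasible(self, x: np.ndarray, tol: float = 1e-6) -> bool:
        scale = max(1.0, abs(self.eer_kj))
        return bool(
            np.all(x >= self.lb - tol)
            and np.all(x <= self.ub + tol)
            and self.energy(x) <= self.eer_kj + tol * scale
        )


def _starts(prob: _Problem, rng: np.random.Generator, n_random: int) -> list[np.ndarray]:
    """Deterministic anchors plus seeded random feasible points."""
    starts: list[np.ndarray] = []
    lb, ub, e, eer = prob.lb, prob.ub, prob.e, prob.eer_kj
    base = lb.copy()
    if prob.energy(base) <= 1e-9:
        base = np.minimum(lb + 0.5, ub)  # nudge off the zero-energy corner
    starts.append(np.clip(base, lb, ub))

    # energy-scaled start: move from the minima toward the cap along all groups
    head = eer - prob.energy(lb)
    if head > 0:
        free = np.isfinite(ub)
        direction = np.where(free, np.minimum(ub - lb, 50.0), 1.0)
        denom = float(e @ direction)
        if denom > 0:
            t = min(1.0, 0.95 * head / denom)
            starts.append(np.clip(lb + t * direction, lb, ub))

    for _ in range(n_random):
        cap = np.where(np.isfinite(ub), ub, np.minimum(eer / np.maximum(e, 1e-9), 1e3))
        x = lb + rng.random(len(lb)) * np.maximum(cap - lb, 0.0)
        # scale back toward the minima if over the energy cap
        E = prob.energy(x)
        Emin = prob.energy(lb)
        if E > eer and E > Emin:
            t = (eer - Emin) / (E - Emin)
            x = lb + max(t, 0.0) * 0.98 * (x - lb)
        if prob.energy(x) <= 1e-9:
            x = np.minimum(lb + 0.25, cap)
        starts.append(np.clip(x, lb, ub))
    return starts


def solve(
    cfg: StudyConfig,
    table: FoodTable,
    eer_kj: float,
    seed: int = 0,
    n_starts: int = 8,
    grid: Optional[float] = None,
) -> SolveResult:
    """Solve for the serving prescription of one participant.

    Minimizes the macronutrient-percentage distance subject to the serving
    bounds and the energy cap, then (tie-break) maximizes total energy
    within the optimal-distance set. Deterministic for a fixed seed. The
    returned result carries both the continuous optimum and its rounded
    counterpart on the serving grid.

    Parameters
    ----------
    cfg : study configuration (targets + serving constraints)
    table : food-group composition table
    eer_kj : participant's estimated energy requirement, kJ/day
    seed : seeds the random restarts
    n_starts : random restarts on top of the deterministic anchors
        (capped at ``MAX_RESTARTS``)
    grid : override for the rounding increment of every group
    """
    prob = _Problem(cfg, table, eer_kj)
    lb_energy = prob.energy(prob.lb)
    if lb_energy > eer_kj * (1 + 1e-9):
        return SolveResult(
            status=SolveStatus.INFEASIBLE,
            infeasibility_margin_kj=lb_energy - eer_kj,
            diagnostics={
                "reason": "serving minima alone exceed the energy cap",
                "minima_energy_kj": lb_energy,
                "eer_kj": eer_kj,
            },
        )

    rng = np.random.default_rng(seed)
    bounds = list(zip(prob.lb, np.where(np.isfinite(prob.ub), prob.ub, None)))
    energy_con = {
        "type": "ineq",
        "fun": lambda x: eer_kj - prob.e @ x,
        "jac": lambda x: -prob.e,
    }
    best_x: Optional[np.ndarray] = None
    best_sq = np.inf
    n_attempted = 0
    for x0 in _starts(prob, rng, min(n_starts, MAX_RESTARTS)):
        n_attempted += 1
        res = minimize(
            prob.sq_distance,
            x0,
            jac=prob.sq_distance_grad,
            bounds=bounds,
            constraints=[energy_con],
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if not prob.feasible(res.x):
            continue
        if res.fun < best_sq:
            best_sq, best_x = float(res.fun), res.x.copy()
        if best_sq < DISTANCE_TOL**2:
            break
    if best_x is None:
        return SolveResult(
            status=SolveStatus.NOT_CONVERGED,
            diagnostics={"restarts": n_attempted, "reason": "no feasible iterate found"},
        )

    # Tie-break phase: maximize energy while holding the distance at its optimum.
    sq_cap = best_sq + max(1e-10, 1e-9 * best_sq)
    dist_con = NonlinearConstraint(
        prob.sq_distance, -np.inf, sq_cap, jac=prob.sq_distance_grad
    )
    res2 = minimize(
        lambda x: -(prob.e @ x) / max(eer_kj, 1.0),
        best_x,
        jac=lambda x: -prob.e / max(eer_kj, 1.0),
        bounds=bounds,
        constraints=[energy_con, dist_con],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    tie_break_applied = False
    if (
        prob.feasible(res2.x)
        and prob.sq_distance(res2.x) <= sq_cap + 1e-9
        and prob.energy(res2.x) > prob.energy(best_x)
    ):
        # polish: re-minimize the distance at the energy level the
        # tie-break reached, so the secondary objective cannot degrade
        # the primary one
        e2 = prob.energy(res2.x)
        floor_con = {
            "type": "ineq",
            "fun": lambda x: prob.e @ x - e2 * (1 - 1e-9),
            "jac": lambda x: prob.e,
        }
        res3 = minimize(
            prob.sq_distance,
            res2.x,
            jac=prob.sq_distance_grad,
            bounds=bounds,
            constraints=[energy_con, floor_con],
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-14},
        )
        candidate = res3.x if prob.feasible(res3.x) else res2.x
        cand_sq = prob.sq_distance(candidate)
        if cand_sq <= best_sq + max(1e-12, 1e-9 * best_sq):
            best_x = candidate.copy()
            best_sq = cand_sq
            tie_break_applied = True

    best_x = np.clip(best_x, prob.lb, prob.ub)
    # SLSQP satisfies constraints only to its own tolerance; shrink any
    # residual cap overshoot away along the ray from the minima (the
    # distance effect is at the constraint-tolerance scale)
    E = prob.energy(best_x)
    if E > eer_kj and E > lb_energy:
        t = (eer_kj - lb_energy) / (E - lb_energy)
        best_x = prob.lb + max(t, 0.0) * (best_x - prob.lb)
        best_sq = prob.sq_distance(best_x)
    prescription = Prescription(
        servings={g: float(v) for g, v in zip(prob.group_ids, best_x)}
    )
    totals = diet_totals(prescription, table)
    distance = math.sqrt(max(best_sq, 0.0))

    rounding = round_prescription(prescription, cfg, table, eer_kj, grid=grid)
    rounded_totals = diet_totals(rounding.prescription, table)
    rounded_distance = (
        macro_distance(rounded_totals, cfg.targets) if rounded_totals.defined else None
    )
    return SolveResult(
        status=SolveStatus.OPTIMAL,
        prescription=prescription,
        totals=totals,
        distance=distance,
        rounded=rounding.prescription,
        rounded_totals=rounded_totals,
        rounded_distance=rounded_distance,
        diagnostics={
            "restarts": n_attempted,
            "tie_break_applied": tie_break_applied,
            "rounding_energy_change_kj": rounding.energy_change_kj,
            "rounding_feasible": rounding.feasible,
            "rounding_warning": rounding.warning,
            "seed": seed,
        },
    )


def brute_force_solve(
    cfg: StudyConfig,
    table: FoodTable,
    eer_kj: float,
    grid: float = 0.5,
    max_points: int = 10**7,
) -> SolveResult:
    """Exhaustive grid-enumeration oracle for small instances (<= 5 groups).

    Enumerates servings on ``lb + k*grid`` per group, upper-bounded by the
    configured maximum or the first grid point whose solo energy exceeds
    the cap, and returns the feasible point of minimal distance
    (energy-maximal among ties). Refuses grids above ``max_points``.
    """
    prob = _Problem(cfg, table, eer_kj)
    n = len(prob.group_ids)
    if n > 5:
        raise ValidationFailure(
            f"brute_force_solve is an oracle for <= 5 groups, got {n}"
        )
    axes = []
    for i in range(n):
        hi = prob.ub[i]
        if not np.isfinite(hi):
            # first grid point whose solo energy exceeds the cap
            if prob.e[i] <= 0:
                hi = prob.lb[i] + 50 * grid  # energy-free group: bounded window
            else:
                steps = math.floor(eer_kj / prob.e[i] / grid) + 1
                hi = steps * grid
        k = int(math.floor((hi - prob.lb[i]) / grid + 1e-9))
        axes.append(prob.lb[i] + grid * np.arange(k + 1))
    total = math.prod(len(a) for a in axes)
    if total > max_points:
        raise ValidationFailure(
            f"grid of {total} points exceeds {max_points}; coarsen the grid "
            f"or bound the groups"
        )
    if total == 0:
        return SolveResult(
            status=SolveStatus.INFEASIBLE,
            infeasibility_margin_kj=prob.energy(prob.lb) - eer_kj,
            diagnostics={"reason": "empty grid"},
        )
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([m.ravel() for m in mesh], axis=1)  # total x n
    energies = X @ prob.e
    feas = energies <= eer_kj + 1e-9
    if not np.any(feas):
        return SolveResult(
            status=SolveStatus.INFEASIBLE,
            infeasibility_margin_kj=float(energies.min() - eer_kj),
            diagnostics={"reason": "no feasible grid point", "points": int(total)},
        )
    Xf, Ef = X[feas], energies[feas]
    grams = Xf @ prob.C.T  # m x 3
    parts = grams * _ENERGY_FACTORS[None, :]
    Etot = parts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(Etot[:, None] > 0, parts / Etot[:, None] * 100.0, 0.0)
    dist = np.linalg.norm(pct - prob.targets[None, :], axis=1)
    dist = np.where(Etot > 0, dist, np.inf)
    if not np.any(np.isfinite(dist)):
        # only the zero-energy corner is feasible
        dist = np.zeros_like(dist)
    dmin = dist.min()
    ties = dist <= dmin + 1e-9
    winner = np.flatnonzero(ties)[np.argmax(Ef[ties])]
    xbest = Xf[winner]
    prescription = Prescription(
        servings={g: float(v) for g, v in zip(prob.group_ids, xbest)}
    )
    totals = diet_totals(prescription, table)
    return SolveResult(
        status=SolveStatus.OPTIMAL,
        prescription=prescription,
        totals=totals,
        distance=float(dmin) if math.isfinite(dmin) else None,
        diagnostics={"points": int(total), "feasible_points": int(feas.sum())},
    )


def _snap(value: float, increment: float, lo: float, hi: float) -> float:
    """Nearest grid multiple within [lo, hi]; ties round up."""
    k = math.floor(value / increment + 0.5 + 1e-12)
    v = k * increment
    while v < lo - 1e-12:
        v += increment
    while v > hi + 1e-12:
        v -= increment
    return v


def round_prescription(
    x: Prescription,
    cfg: StudyConfig,
    table: FoodTable,
    eer_kj: float,
    grid: Optional[float] = None,
) -> RoundingResult:
    """Snap a feasible prescription to the serving grid and repair.

    Each group's servings move to the nearest multiple of its increment
    (default half servings; whole servings with ``integral``), except
    weekly-frequency groups (those with a practical ``weekly_unit_g``,
    e.g. fish), whose fractional daily servings encode whole weekly
    portions and are left continuous. The repair pass restores minima and,
    if the snapped diet breaches the energy cap, steps the largest
    upward-rounded groups back down. When no feasible rounding exists the
    continuous values are returned with a warning.
    """
    prob = _Problem(cfg, table, eer_kj)
    servings = dict(x.servings)
    snapped: dict[str, float] = {}
    rounded_up: list[str] = []
    for i, gid in enumerate(prob.group_ids):
        v = servings.get(gid, 0.0)
        c = cfg.constraint_for(gid)
        group = table[gid]
        if group.weekly_unit_g is not None:
            snapped[gid] = v  # weekly-frequency group: keep continuous
            continue
        inc = grid if grid is not None else (c.rounding_increment if c else 0.5)
        lo, hi = prob.lb[i], prob.ub[i]
        sv = _snap(v, inc, lo, hi)
        if sv < lo - 1e-12 or sv > hi + 1e-12:
            # grid and bounds incompatible for this group
            return RoundingResult(
                prescription=x,
                energy_change_kj=0.0,
                feasible=False,
                warning=f"no grid point within bounds for group {gid!r}",
            )
        snapped[gid] = sv
        if sv > v + 1e-12:
            rounded_up.append(gid)
    # carry any groups present in x but absent from the table order (none normally)
    for gid, v in servings.items():
        snapped.setdefault(gid, v)

    e_by_gid = dict(zip(prob.group_ids, prob.e))
    idx = {g: i for i, g in enumerate(prob.group_ids)}

    def total_energy(s: dict[str, float]) -> float:
        return sum(e_by_gid.get(g, 0.0) * v for g, v in s.items())

    # repair: if over the cap, walk upward-rounded groups back down one
    # increment at a time, largest energy offender first
    guard = 0
    while total_energy(snapped) > eer_kj + 1e-9 and guard < 1000:
        guard += 1
        candidates = []
        for gid in rounded_up:
            c = cfg.constraint_for(gid)
            inc = grid if grid is not None else (c.rounding_increment if c else 0.5)
            lo = prob.lb[idx[gid]]
            if snapped[gid] - inc >= lo - 1e-12:
                candidates.append((e_by_gid.get(gid, 0.0) * inc, gid, inc))
        if not candidates:
            return RoundingResult(
                prescription=x,
                energy_change_kj=0.0,
                feasible=False,
                warning=(
                    "rounding up breaches the energy cap and rounding down "
                    "breaches a serving minimum; continuous values retained"
                ),
            )
        candidates.sort(reverse=True)
        _, gid, inc = candidates[0]
        snapped[gid] -= inc

    original_energy = total_energy(servings)
    rounded = Prescription(servings={g: float(v) for g, v in snapped.items()})
    return RoundingResult(
        prescription=rounded,
        energy_change_kj=total_energy(snapped) - original_energy,
        feasible=True,
        warning=None,
    )
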