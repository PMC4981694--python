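"""Diet totals, the distance objective, the solver and its grid oracle."""

import math

import numpy as np
import pytest

from dietmodel.foodspec import (
    FoodGroup,
    FoodTable,
    NutrientProfile,
    ValidationFailure,
)
from dietmodel.optimizer import (
    Prescription,
    SolveStatus,
    brute_force_solve,
    diet_totals,
    macro_distance,
    round_prescription,
    solve,
)
from dietmodel.studyconfig import MacroTargets, ServingConstraint, StudyConfig
from dietmodel.synthetic import (
    PURE_MACRO_EER_KJ,
    PURE_MACRO_OPTIMUM,
    pure_macro_config,
    pure_macro_table,
    random_instance,
)

TARGETS = MacroTargets(target_cho_pct=50, target_ptn_pct=20, target_fat_pct=30)


def _single_group_table(cho=15.0, ptn=5.0, fat=2.0, gid="g"):
    return FoodTable(
        [
            FoodGroup(
                group_id=gid,
                name=gid,
                serving_size_g=50,
                profile=NutrientProfile(cho_g=cho, ptn_g=ptn, fat_g=fat),
            )
        ]
    )


class TestDietTotals:
    def test_hand_arithmetic(self):
        table = _single_group_table()
        t = diet_totals(Prescription.of(g=2.0), table)
        assert (t.total_cho_g, t.total_ptn_g, t.total_fat_g) == (30, 10, 4)
        # 17*30 + 17*10 + 36*4 kJ
        assert t.total_energy_kj == pytest.approx(824)
        assert t.pct_cho == pytest.approx(100 * 510 / 824)
        assert t.pct_ptn == pytest.approx(100 * 170 / 824)
        assert t.pct_fat == pytest.approx(100 * 144 / 824)

    def test_zero_diet_has_undefined_percentages(self):
        t = diet_totals(Prescription.of(g=0.0), _single_group_table())
        assert t.total_energy_kj == 0 and not t.defined
        with pytest.raises(ValidationFailure):
            t.percentages()

    def test_doubling_preserves_percentages(self):
        table = _single_group_table()
        t1 = diet_totals(Prescription.of(g=2.0), table)
        t2 = diet_totals(Prescription.of(g=4.0), table)
        assert t2.total_energy_kj == pytest.approx(2 * t1.total_energy_kj)
        assert t2.pct_cho == pytest.approx(t1.pct_cho)

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            diet_totals(Prescription.of(phantom=1.0), _single_group_table())

    def test_percentage_closure(self, rng):
        table = _single_group_table(
            *(rng.uniform(0.5, 20, size=3))
        )
        for _ in range(20):
            t = diet_totals(Prescription.of(g=float(rng.uniform(0.1, 20))), table)
            assert sum(t.percentages()) == pytest.approx(100, abs=1e-9)


class TestMacroDistance:
    def test_exact_match_is_zero(self):
        t = diet_totals(
            Prescription.of(
                c=50 / 17, p=20 / 17, f=30 / 36
            ),  # 1 g of each macro per serving
            FoodTable(
                [
                    FoodGroup(
                        group_id=gid,
                        name=gid,
                        serving_size_g=10,
                        profile=NutrientProfile(
                            cho_g=1.0 * (gid == "c"),
                            ptn_g=1.0 * (gid == "p"),
                            fat_g=1.0 * (gid == "f"),
                        ),
                    )
                    for gid in ("c", "p", "f")
                ]
            ),
        )
        assert macro_distance(t, TARGETS) == pytest.approx(0, abs=1e-12)

    def test_symmetric_three_point_deviation(self):
        from dietmodel.optimizer import DietTotals

        t = DietTotals(
            total_cho_g=1,
            total_ptn_g=1,
            total_fat_g=1,
            total_energy_kj=100,
            pct_cho=53.0,
            pct_ptn=20.0,
            pct_fat=27.0,
        )
        assert macro_distance(t, TARGETS) == pytest.approx(math.sqrt(18))
        assert macro_distance(t, TARGETS) == pytest.approx(4.2426, abs=1e-4)

    def test_hand_value_on_diet_example(self):
        t = diet_totals(Prescription.of(g=2.0), _single_group_table())
        expected = math.sqrt(
            (100 * 510 / 824 - 50) ** 2
            + (100 * 170 / 824 - 20) ** 2
            + (100 * 144 / 824 - 30) ** 2
        )
        assert macro_distance(t, TARGETS) == pytest.approx(expected)
        assert expected == pytest.approx(17.283, abs=1e-3)


class TestSolve:
    def test_exact_recovery_with_energy_tie_break(self, pure_config, pure_table):
        r = solve(pure_config, pure_table, PURE_MACRO_EER_KJ, seed=1)
        assert r.status is SolveStatus.OPTIMAL
        assert r.distance < 1e-6
        for gid, expected in PURE_MACRO_OPTIMUM.items():
            assert r.prescription.servings[gid] == pytest.approx(expected, abs=1e-3)
        assert r.totals.total_energy_kj == pytest.approx(PURE_MACRO_EER_KJ)

    def test_minima_exceeding_cap_is_infeasible(self):
        table = _single_group_table(cho=100 / 17, ptn=0, fat=0)  # 100 kJ/serving
        cfg = StudyConfig(
            study_id="s",
            targets=TARGETS,
            constraints=(ServingConstraint(group_id="g", min_servings=10),),
        )
        r = solve(cfg, table, eer_kj=500)
        assert r.status is SolveStatus.INFEASIBLE
        assert r.infeasibility_margin_kj == pytest.approx(500)

    def test_optimum_at_minima_fixed_point(self, pure_table):
        cfg = StudyConfig(
            study_id="fixed",
            targets=TARGETS,
            constraints=tuple(
                ServingConstraint(group_id=g, min_servings=v)
                for g, v in PURE_MACRO_OPTIMUM.items()
            ),
        )
        r = solve(cfg, pure_table, PURE_MACRO_EER_KJ, seed=0)
        assert r.status is SolveStatus.OPTIMAL
        assert r.distance < 1e-6
        for gid, expected in PURE_MACRO_OPTIMUM.items():
            assert r.prescription.servings[gid] == pytest.approx(expected, abs=1e-6)

    def test_deterministic_for_fixed_seed(self, rng):
        cfg, table, eer = random_instance(rng)
        a = solve(cfg, table, eer, seed=11)
        b = solve(cfg, table, eer, seed=11)
        assert a.prescription == b.prescription
        assert a.distance == b.distance and a.rounded == b.rounded

    def test_profile_scaling_leaves_percentages_unchanged(self, rng):
        cfg, table, eer = random_instance(rng, n_groups=3)
        c = 2.5  # halve the serving granularity: per-serving grams scale by c
        scaled = FoodTable(
            [
                g.model_copy(
                    update={
                        "profile": g.profile.scaled(c),
                        "serving_size_g": g.serving_size_g * c,
                    }
                )
                for g in table
            ]
        )
        scaled_cfg = cfg.model_copy(
            update={
                "constraints": tuple(
                    k.model_copy(
                        update={
                            "min_servings": k.min_servings / c,
                            "max_servings": (
                                None if k.max_servings is None else k.max_servings / c
                            ),
                            "increment": k.increment / c,
                        }
                    )
                    for k in cfg.constraints
                )
            }
        )
        a = solve(cfg, table, eer, seed=5)
        b = solve(scaled_cfg, scaled, eer, seed=5)
        assert a.status is b.status is SolveStatus.OPTIMAL
        assert b.totals.pct_cho == pytest.approx(a.totals.pct_cho, abs=1e-4)
        assert b.totals.pct_fat == pytest.approx(a.totals.pct_fat, abs=1e-4)

    def test_feasibility_of_optimal_results(self, rng):
        for i in range(25):
            cfg, table, eer = random_instance(rng)
            r = solve(cfg, table, eer, seed=i)
            assert r.status is SolveStatus.OPTIMAL
            for c in cfg.constraints:
                v = r.prescription.servings[c.group_id]
                assert v >= c.min_servings - 1e-9
                if c.effective_max is not None:
                    assert v <= c.effective_max + 1e-9
            assert r.totals.total_energy_kj <= eer + 1e-9 * max(1.0, eer)


class TestBruteForceOracle:
    def test_pure_instance_on_third_grid(self, pure_config, pure_table):
        bf = brute_force_solve(pure_config, pure_table, PURE_MACRO_EER_KJ, grid=1 / 3)
        assert bf.status is SolveStatus.OPTIMAL
        assert bf.distance == pytest.approx(0, abs=1e-9)
        for gid, expected in PURE_MACRO_OPTIMUM.items():
            assert bf.prescription.servings[gid] == pytest.approx(expected, abs=1e-9)

    def test_infeasibility_agrees_with_solver(self):
        table = _single_group_table(cho=100 / 17, ptn=0, fat=0)
        cfg = StudyConfig(
            study_id="s",
            targets=TARGETS,
            constraints=(ServingConstraint(group_id="g", min_servings=10),),
        )
        assert (
            brute_force_solve(cfg, table, 500).status
            is solve(cfg, table, 500).status
            is SolveStatus.INFEASIBLE
        )

    def test_solver_dominates_grid_oracle(self, rng):
        for i in range(10):
            cfg, table, eer = random_instance(rng, n_groups=2, small_energy=True)
            r = solve(cfg, table, eer, seed=i)
            bf = brute_force_solve(cfg, table, eer, grid=0.5)
            assert r.distance <= bf.distance + 1e-6

    def test_refuses_oversized_grid(self, pure_config, pure_table):
        with pytest.raises(ValidationFailure, match="coarsen"):
            brute_force_solve(
                pure_config, pure_table, PURE_MACRO_EER_KJ, grid=0.001
            )


class TestRounding:
    def test_worked_half_serving_snap(self, pure_config, pure_table):
        x = Prescription.of(cho_pure=10.0, ptn_pure=4.0, fat_pure=17 / 3)
        res = round_prescription(x, pure_config, pure_table, PURE_MACRO_EER_KJ)
        assert res.prescription.servings == {
            "cho_pure": 10.0,
            "ptn_pure": 4.0,
            "fat_pure": 5.5,
        }
        # the fat group carries 180 kJ/serving; snapping 5.667 -> 5.5 sheds 30 kJ
        assert res.energy_change_kj == pytest.approx(-30.0, abs=1e-9)
        assert res.feasible

    def test_on_grid_input_unchanged(self, pure_config, pure_table):
        x = Prescription.of(cho_pure=10.0, ptn_pure=4.0, fat_pure=5.5)
        res = round_prescription(x, pure_config, pure_table, PURE_MACRO_EER_KJ)
        assert res.prescription == x and res.energy_change_kj == 0

    def test_conflicting_grid_keeps_continuous_with_warning(self):
        table = _single_group_table(cho=100 / 17, ptn=0, fat=0)  # 100 kJ/serving
        cfg = StudyConfig(
            study_id="s",
            targets=TARGETS,
            constraints=(ServingConstraint(group_id="g", min_servings=0.3),),
        )
        # x = 0.3 is feasible at cap 35 kJ; snapping up to 0.5 breaches the
        # cap and snapping down to 0 breaches the minimum
        x = Prescription.of(g=0.3)
        res = round_prescription(x, cfg, table, eer_kj=35)
        assert not res.feasible and res.warning is not None
        assert res.prescription == x

    def test_weekly_frequency_groups_not_snapped(self):
        table = FoodTable(
            [
                FoodGroup(
                    group_id="fish",
                    name="Oily fish",
                    serving_size_g=30,
                    profile=NutrientProfile(cho_g=0, ptn_g=7, fat_g=3),
                    weekly_unit_g=90,
                ),
                FoodGroup(
                    group_id="veg",
                    name="Veg",
                    serving_size_g=75,
                    profile=NutrientProfile(cho_g=3.5, ptn_g=1.5, fat_g=0.2),
                ),
            ]
        )
        cfg = StudyConfig(
            study_id="s",
            targets=TARGETS,
            constraints=(
                ServingConstraint(group_id="fish", min_servings=0.43),
                ServingConstraint(group_id="veg"),
            ),
        )
        x = Prescription.of(fish=0.43, veg=5.2)
        res = round_prescription(x, cfg, table, eer_kj=5000)
        assert res.prescription.servings["fish"] == 0.43  # one portion/week kept
        assert res.prescription.servings["veg"] == 5.0
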