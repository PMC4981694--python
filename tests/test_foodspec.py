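"""Food table I/O and within-group nutrient statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dietmodel.foodspec import (
    FoodItem,
    FoodTable,
    Nutrient,
    NutrientProfile,
    SchemaError,
    ValidationFailure,
    VariationFlag,
    flag_high_variation,
    group_statistics,
    load_food_table,
    rank_primary_sources,
    statistics_by_group,
    write_food_table,
)

VEG_GRAINS_CSV = """group_id,name,serving_size_g,cho_g,ptn_g,fat_g
veg,Vegetables,75,3,2,0.3
grains,Grains,40,15,3,1
"""


def _items(group_id, cho_values):
    return [
        FoodItem(
            item_id=f"{group_id}_{k}",
            group_id=group_id,
            profile_per_100g=NutrientProfile(cho_g=v, ptn_g=1.0, fat_g=0.5),
        )
        for k, v in enumerate(cho_values)
    ]


class TestFoodTableIO:
    def test_parse_two_groups(self, tmp_path):
        p = tmp_path / "foods.csv"
        p.write_text(VEG_GRAINS_CSV)
        table = load_food_table(p)
        assert len(table) == 2
        assert table["veg"].profile.cho_g == 3
        assert table["grains"].serving_size_g == 40

    def test_header_only_is_empty_table(self, tmp_path):
        p = tmp_path / "foods.csv"
        p.write_text("group_id,name,serving_size_g,cho_g,ptn_g,fat_g\n")
        assert len(load_food_table(p)) == 0

    def test_negative_nutrient_cites_row(self, tmp_path):
        p = tmp_path / "foods.csv"
        p.write_text(
            "group_id,name,serving_size_g,cho_g,ptn_g,fat_g\n"
            "veg,Vegetables,75,3,2,0.3\n"
            "bad,Bad,40,-1,3,1\n"
        )
        with pytest.raises(ValidationFailure, match="line 3"):
            load_food_table(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "foods.csv"
        p.write_text("group_id,name,serving_size_g,cho_g,ptn_g\nveg,V,75,3,2\n")
        with pytest.raises(SchemaError, match="fat_g"):
            load_food_table(p)

    def test_duplicate_group_id_rejected(self, tmp_path):
        p = tmp_path / "foods.csv"
        p.write_text(
            "group_id,name,serving_size_g,cho_g,ptn_g,fat_g\n"
            "veg,V,75,3,2,0.3\nveg,V2,75,3,2,0.3\n"
        )
        with pytest.raises(ValidationFailure, match="duplicate"):
            load_food_table(p)

    def test_load_write_load_round_trip(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        p1.write_text(VEG_GRAINS_CSV)
        table = load_food_table(p1)
        write_food_table(table, p2)
        assert load_food_table(p2) == table
        # and a second pass is byte-stable
        p3 = tmp_path / "c.csv"
        write_food_table(load_food_table(p2), p3)
        assert p2.read_bytes() == p3.read_bytes()

    def test_fat_subclass_closure_enforced(self):
        with pytest.raises(ValueError, match="subclasses"):
            NutrientProfile(cho_g=0, ptn_g=0, fat_g=5, sat_g=2, mufa_g=2, pufa_g=2)


class TestGroupStatistics:
    def test_hand_computed_dispersion(self):
        s = group_statistics(_items("g", [10, 12, 14]), Nutrient.CHO)
        assert s.mean == pytest.approx(12)
        assert s.sd == pytest.approx(2)  # sample (n-1) denominator
        assert s.value_range == pytest.approx(4)
        assert s.cv == pytest.approx(100 * 2 / 12)

    def test_zero_variance(self):
        s = group_statistics(_items("g", [8, 8, 8]), Nutrient.CHO)
        assert s.sd == 0 and s.cv == 0 and s.value_range == 0

    def test_cv_scale_invariance_example(self):
        a = group_statistics(_items("g", [10, 12, 14]), Nutrient.CHO)
        b = group_statistics(_items("g", [30, 36, 42]), Nutrient.CHO)
        assert b.cv == pytest.approx(a.cv)

    @given(
        st.lists(st.floats(0.1, 1e3), min_size=2, max_size=12),
        st.floats(1e-3, 1e3),
    )
    def test_cv_invariant_under_positive_scaling(self, values, c):
        base = group_statistics(_items("g", values), Nutrient.CHO)
        scaled = group_statistics(_items("g", [v * c for v in values]), Nutrient.CHO)
        if base.cv_defined:
            assert scaled.cv == pytest.approx(base.cv, rel=1e-9, abs=1e-9)

    @given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=10))
    def test_range_zero_iff_all_equal(self, values):
        s = group_statistics(_items("g", values), Nutrient.CHO)
        assert (s.value_range == 0) == (len(set(values)) == 1)
        assert s.sd >= 0 and s.value_range >= 0

    def test_single_item_degenerate(self):
        s = group_statistics(_items("g", [7.0]), Nutrient.CHO)
        assert s.sd == 0 and s.value_range == 0 and s.cv == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationFailure):
            group_statistics([], Nutrient.CHO)

    def test_mixed_groups_rejected(self):
        items = _items("a", [1, 2]) + _items("b", [1, 2])
        with pytest.raises(ValidationFailure, match="statistics_by_group"):
            group_statistics(items, Nutrient.CHO)
        assert set(statistics_by_group(items, Nutrient.CHO)) == {"a", "b"}

    def test_zero_mean_cv_undefined(self):
        items = [
            FoodItem(
                item_id=f"i{k}",
                group_id="g",
                profile_per_100g=NutrientProfile(cho_g=0, ptn_g=1, fat_g=0),
            )
            for k in range(3)
        ]
        s = group_statistics(items, Nutrient.CHO)
        assert not s.cv_defined and s.cv is None


class TestVariationScreen:
    def test_cv_above_threshold_excessive(self):
        s = group_statistics(_items("g", [10, 12, 14]), Nutrient.CHO)  # cv 16.67
        assert flag_high_variation(s) is VariationFlag.EXCESSIVE

    def test_cv_zero_acceptable(self):
        s = group_statistics(_items("g", [8, 8, 8]), Nutrient.CHO)
        assert flag_high_variation(s) is VariationFlag.ACCEPTABLE

    def test_boundary_is_strict(self):
        # construct cv exactly 15: mean 10, sd 1.5 -> values 10 +/- 1.5
        values = [8.5, 10.0, 11.5]
        s = group_statistics(_items("g", values), Nutrient.CHO)
        assert s.cv == pytest.approx(15.0)
        assert flag_high_variation(s, threshold=s.cv) is VariationFlag.EXCESSIVE

    def test_undefined_cv_goes_to_manual_review(self):
        items = [
            FoodItem(
                item_id=f"i{k}",
                group_id="g",
                profile_per_100g=NutrientProfile(cho_g=0, ptn_g=1, fat_g=0),
            )
            for k in range(2)
        ]
        s = group_statistics(items, Nutrient.CHO)
        assert flag_high_variation(s) is VariationFlag.NEEDS_MANUAL_COMPARISON


class TestPrimarySources:
    @staticmethod
    def _pool(shares):
        items = []
        for k, share in enumerate(shares):
            items.extend(_items(f"g{k + 1}", [share * 100]))
        return items

    def test_prefix_stops_below_cutoff(self):
        r = rank_primary_sources(self._pool([0.50, 0.20, 0.20, 0.10]), Nutrient.CHO)
        assert r.primary_groups == ["g1", "g2"]
        assert r.cumulative[1] == pytest.approx(0.70)

    def test_single_dominant_group_warns(self):
        r = rank_primary_sources(self._pool([1.0]), Nutrient.CHO)
        assert r.primary_groups == [] and r.warning is not None

    def test_boundary_share_just_below_cutoff(self):
        r = rank_primary_sources(self._pool([0.74, 0.26]), Nutrient.CHO)
        assert r.primary_groups == ["g1"]

    def test_all_zero_contributions_rejected(self):
        items = [
            FoodItem(
                item_id="i1",
                group_id="g1",
                profile_per_100g=NutrientProfile(cho_g=0, ptn_g=1, fat_g=0),
            )
        ]
        with pytest.raises(ValidationFailure):
            rank_primary_sources(items, Nutrient.CHO)

    def test_shares_sum_to_one(self, rng):
        shares = rng.dirichlet(np.ones(6))
        r = rank_primary_sources(self._pool(shares), Nutrient.CHO)
        assert math.isclose(sum(r.shares), 1.0, abs_tol=1e-12)
        assert r.cumulative == sorted(r.cumulative)
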