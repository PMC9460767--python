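import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import heisnutr as hn
from heisnutr.errors import DegenerateDataError, ValidationError
from heisnutr.nutrients import NUTRIENTS
from heisnutr.table_builder import (
    aggregate_category,
    drop_multi_outlier_items,
    flag_outliers,
)

from conftest import flags_by_hand, make_food_item, quartiles_by_hand


class TestComputeRae:
    @pytest.mark.parametrize(
        "retinol, beta, other, expected",
        [
            (100.0, 0.0, 0.0, 100.0),  # retinol is already RAE
            (0.0, 1200.0, 0.0, 100.0),  # beta-carotene / 12
            (50.0, 600.0, 240.0, 110.0),  # 50 + 50 + 10
        ],
    )
    def test_known_values(self, retinol, beta, other, expected):
        assert hn.compute_rae(retinol, beta, other) == pytest.approx(expected)

    def test_partial_missing_contributes_nothing(self):
        assert hn.compute_rae(100.0, np.nan, np.nan) == pytest.approx(100.0)

    def test_all_missing_is_missing(self):
        assert np.isnan(hn.compute_rae(np.nan, np.nan, np.nan))

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            hn.compute_rae(-1.0, 0.0, 0.0)


class TestStandardize:
    @pytest.mark.parametrize(
        "portion, column, amount, density",
        [
            (50.0, "energy_kcal", 80.0, 160.0),
            (100.0, "energy_kcal", 80.0, 80.0),
            (250.0, "iron_mg", 5.0, 2.0),
        ],
    )
    def test_density_scaling(self, portion, column, amount, density):
        items = pd.DataFrame([make_food_item(portion_mass_g=portion, **{column: amount})])
        std = hn.standardize_items(items)
        canonical = {"energy_kcal": "energy_kcal", "iron_mg": "fe_mg"}[column]
        assert std.loc[0, canonical] == pytest.approx(density)

    def test_missing_stays_missing(self):
        items = pd.DataFrame([make_food_item(vitamin_c_mg=np.nan)])
        assert np.isnan(hn.standardize_items(items).loc[0, "vitc_mg"])

    @given(c=st.floats(min_value=0.01, max_value=100.0, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_portion_rescaling_invariance(self, c):
        base = make_food_item(
            portion_mass_g=120.0,
            energy_kcal=55.0,
            protein_g=3.0,
            retinol_ug=10.0,
            beta_carotene_ug=120.0,
            other_provitamin_a_ug=48.0,
            vitamin_c_mg=7.0,
            iron_mg=1.1,
            zinc_mg=0.4,
        )
        scaled = dict(base)
        scaled["portion_mass_g"] = base["portion_mass_g"] * c
        for col in (
            "energy_kcal",
            "protein_g",
            "retinol_ug",
            "beta_carotene_ug",
            "other_provitamin_a_ug",
            "vitamin_c_mg",
            "iron_mg",
            "zinc_mg",
        ):
            scaled[col] = base[col] * c
        a = hn.standardize_items(pd.DataFrame([base]))
        b = hn.standardize_items(pd.DataFrame([scaled]))
        np.testing.assert_allclose(
            a[list(NUTRIENTS)].to_numpy(), b[list(NUTRIENTS)].to_numpy(), rtol=1e-9
        )


class TestTukeyFence:
    def test_fence_formula(self):
        fence = hn.Fence(q1=10.0, q3=20.0)
        assert fence.iqr == 10.0
        assert fence.lower == -5.0
        assert fence.upper == 35.0

    def test_degenerate_spread(self):
        fence = hn.tukey_fence([7.0, 7.0, 7.0])
        assert (fence.lower, fence.upper) == (7.0, 7.0)

    def test_matches_hand_interpolated_quartiles(self):
        values = [1.0, 2.0, 3.0, 4.0, 100.0]
        fence = hn.tukey_fence(values)
        q1, q3 = quartiles_by_hand(values)
        assert fence.q1 == pytest.approx(q1)  # = 2.0
        assert fence.q3 == pytest.approx(q3)  # = 4.0
        assert fence.lower == pytest.approx(-1.0)
        assert fence.upper == pytest.approx(7.0)

    def test_all_missing_unbuildable(self):
        with pytest.raises(DegenerateDataError):
            hn.tukey_fence([np.nan, np.nan])


def _category_frame(values_by_nutrient, category="A001"):
    n = max(len(v) for v in values_by_nutrient.values())
    data = {
        "food_id": [f"F{i}" for i in range(n)],
        "source": "SZ",
        "category_key": category,
        "edible_fraction": 0.9,
    }
    for nutrient in NUTRIENTS:
        data[nutrient] = values_by_nutrient.get(nutrient, [1.0] * n)
    return pd.DataFrame(data)


class TestFlagOutliers:
    def test_only_extreme_value_flagged(self):
        std = _category_frame({"fe_mg": [1.0, 2.0, 3.0, 4.0, 100.0]})
        flags = flag_outliers(std)
        assert flags["fe_mg"].tolist() == [False, False, False, False, True]
        assert not flags[[n for n in NUTRIENTS if n != "fe_mg"]].any().any()

    def test_constant_values_never_flagged(self):
        std = _category_frame({"fe_mg": [5.0, 5.0, 5.0, 5.0]})
        assert not flag_outliers(std).any().any()

    def test_value_on_fence_not_flagged(self):
        # fences collapse to [0, 0]; the zeros sit exactly on the fence
        std = _category_frame({"zn_mg": [0.0, 0.0, 0.0, 0.0, 10.0]})
        flags = flag_outliers(std)
        assert flags["zn_mg"].tolist() == [False, False, False, False, True]

    def test_single_item_yields_no_flags(self):
        std = _category_frame({"fe_mg": [42.0]})
        assert not flag_outliers(std).any().any()

    def test_missing_never_flagged(self):
        std = _category_frame({"vitc_mg": [1.0, 1.1, np.nan, 50.0]})
        flags = flag_outliers(std)
        assert not flags.loc[2].any()

    def test_brute_force_oracle_on_random_small_categories(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            n = int(rng.integers(1, 9))
            values = rng.lognormal(0.0, 1.5, size=n)
            values[rng.random(n) < 0.15] = np.nan
            std = _category_frame({"protein_g": values.tolist()})
            flags = flag_outliers(std)
            np.testing.assert_array_equal(
                flags["protein_g"].to_numpy(), flags_by_hand(values)
            )


class TestDropAndAggregate:
    def test_item_with_two_flagged_nutrients_removed(self):
        std = _category_frame(
            {"fe_mg": [1.0, 1.1, 1.2, 1.3, 50.0], "zn_mg": [2.0, 2.1, 2.2, 2.3, 80.0]}
        )
        flags = flag_outliers(std)
        retained, log = drop_multi_outlier_items(std, flags)
        assert "F4" not in set(retained["food_id"])
        assert log.loc[0, "food_id"] == "F4"
        assert set(log.loc[0, "flagged_nutrients"].split(",")) == {"fe_mg", "zn_mg"}

    def test_single_flag_item_retained_but_value_excluded(self):
        std = _category_frame({"fe_mg": [2.0, 4.0, 3.0, 3.5, 100.0]})
        flags = flag_outliers(std)
        retained, log = drop_multi_outlier_items(std, flags)
        assert len(retained) == 5 and log.empty
        profile = aggregate_category(retained, flags, method="mean")
        assert profile["fe_mg"] == pytest.approx(np.mean([2.0, 4.0, 3.0, 3.5]))

    def test_no_flags_is_noop(self):
        std = _category_frame({"fe_mg": [1.0, 1.1, 1.2]})
        flags = flag_outliers(std)
        retained, log = drop_multi_outlier_items(std, flags)
        assert len(retained) == 3 and log.empty

    def test_all_items_dropped_is_error_naming_category(self):
        std = _category_frame({"fe_mg": [1.0]}, category="A077")
        flags = flag_outliers(std)
        flags.loc[:, ["fe_mg", "zn_mg"]] = True  # force the degenerate case
        with pytest.raises(DegenerateDataError, match="A077"):
            drop_multi_outlier_items(std, flags)

    @pytest.mark.parametrize(
        "values, method, expected",
        [
            ([2.0, 4.0, 6.0], "mean", 4.0),
            ([1.0, 2.0, 3.0, 4.0], "median", 2.5),
        ],
    )
    def test_aggregation_arithmetic(self, values, method, expected):
        std = _category_frame({"protein_g": values})
        flags = flag_outliers(std)
        flags.loc[:, :] = False
        profile = aggregate_category(std, flags, method=method)
        assert profile["protein_g"] == pytest.approx(expected)

    def test_mean_excludes_flagged_values(self):
        std = _category_frame({"protein_g": [2.0, 4.0, 100.0]})
        flags = pd.DataFrame(False, index=std.index, columns=list(NUTRIENTS))
        flags.loc[2, "protein_g"] = True
        profile = aggregate_category(std, flags, method="mean")
        assert profile["protein_g"] == pytest.approx(3.0)

    def test_nutrient_with_no_usable_values_emitted_missing(self):
        std = _category_frame({"vitc_mg": [np.nan, np.nan]})
        flags = flag_outliers(std)
        profile = aggregate_category(std, flags)
        assert np.isnan(profile["vitc_mg"])
        assert profile["protein_g"] == pytest.approx(1.0)


class TestBuildConversionTable:
    def test_single_item_category_profile_equals_item(self, small_catalog):
        items = pd.DataFrame(
            [make_food_item(category_key="A001", portion_mass_g=200.0, energy_kcal=300.0)]
        )
        result = hn.build_conversion_table(small_catalog, items)
        row = result.table.set_index("category_key").loc["A001"]
        assert row["energy_kcal"] == pytest.approx(150.0)
        assert row["n_items_retained"] == 1
        assert sorted(result.empty_categories) == ["A002", "A004"]

    def test_pipeline_determinism(self, default_bundle):
        _, catalog, foods, _ = default_bundle
        a = hn.build_conversion_table(catalog, foods)
        b = hn.build_conversion_table(catalog, foods)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.drop_log, b.drop_log)

    def test_mean_equals_median_on_symmetric_items(self, small_catalog):
        # three items per category, densities symmetric around the middle one
        items = []
        for k, key in enumerate(["A001", "A002", "A004"]):
            for j, factor in enumerate([0.9, 1.0, 1.1]):
                kwargs = {
                    col: factor * (10.0 + k)
                    for col in ("energy_kcal", "protein_g", "vitamin_c_mg", "iron_mg", "zinc_mg")
                }
                items.append(
                    make_food_item(
                        food_id=f"F{k}{j}",
                        category_key=key,
                        retinol_ug=factor * 5.0,
                        beta_carotene_ug=0.0,
                        other_provitamin_a_ug=0.0,
                        **kwargs,
                    )
                )
        items = pd.DataFrame(items)
        mean_t = hn.build_conversion_table(small_catalog, items, method="mean").table
        median_t = hn.build_conversion_table(small_catalog, items, method="median").table
        np.testing.assert_allclose(
            mean_t[list(NUTRIENTS)].to_numpy(),
            median_t[list(NUTRIENTS)].to_numpy(),
            atol=1e-9,
        )

    def test_contaminant_dropped_and_effect_bounded(self, small_catalog):
        rng = np.random.default_rng(7)
        clean = pd.DataFrame(
            [
                make_food_item(
                    food_id=f"F{i}",
                    category_key="A001",
                    energy_kcal=100.0 * (1 + 0.05 * rng.standard_normal()),
                    iron_mg=2.0 * (1 + 0.05 * rng.standard_normal()),
                    zinc_mg=1.5 * (1 + 0.05 * rng.standard_normal()),
                )
                for i in range(6)
            ]
        )
        contaminant = make_food_item(
            food_id="BAD",
            category_key="A001",
            energy_kcal=100.0,
            iron_mg=2.0 * 10 * 10,  # >= 10x the category maximum
            zinc_mg=1.5 * 10 * 10,
        )
        dirty = pd.concat([clean, pd.DataFrame([contaminant])], ignore_index=True)
        res_clean = hn.build_conversion_table(small_catalog, clean)
        res_dirty = hn.build_conversion_table(small_catalog, dirty)
        assert "BAD" in set(res_dirty.drop_log["food_id"])
        naive = dirty.pipe(hn.standardize_items)["fe_mg"].mean()
        got = res_dirty.table.set_index("category_key").loc["A001", "fe_mg"]
        ref = res_clean.table.set_index("category_key").loc["A001", "fe_mg"]
        assert abs(got - ref) < abs(naive - ref)

    def test_scale_invariance_of_profiles(self, small_catalog):
        items = pd.DataFrame(
            [
                make_food_item(food_id=f"F{i}", category_key="A001", energy_kcal=50.0 + i)
                for i in range(4)
            ]
        )
        scaled = items.copy()
        c = 3.7
        for col in ("portion_mass_g", *hn.catalog.FOOD_ITEM_COLUMNS[5:]):
            scaled[col] = scaled[col] * c
        a = hn.build_conversion_table(small_catalog, items).table
        b = hn.build_conversion_table(small_catalog, scaled).table
        np.testing.assert_allclose(
            a[list(NUTRIENTS)].to_numpy(), b[list(NUTRIENTS)].to_numpy(), rtol=1e-12
        )
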