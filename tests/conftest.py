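import numpy as np
import pandas as pd
import pytest

import heisnutr as hn
from heisnutr.nutrients import RAW_NUTRIENT_COLUMNS


def make_food_item(
    food_id="F1",
    source="SZ",
    category_key="A001",
    edible_fraction=1.0,
    portion_mass_g=100.0,
    **nutrients,
):
    """One raw food-composition row with sane defaults."""
    row = {
        "food_id": food_id,
        "source": source,
        "category_key": category_key,
        "edible_fraction": edible_fraction,
        "portion_mass_g": portion_mass_g,
    }
    for col in RAW_NUTRIENT_COLUMNS:
        row[col] = nutrients.get(col, 1.0)
    return row


@pytest.fixture
def small_catalog():
    return pd.DataFrame(
        {
            "key": ["A001", "A002", "A003", "A004"],
            "label": ["maize", "beans", "tobacco", "chicken"],
            "nutritive": [True, True, False, True],
        }
    )


@pytest.fixture(scope="session")
def default_bundle():
    """A full default-condition synthetic data set: catalog, foods, truth."""
    config = hn.GeneratorConfig(seed=1)
    catalog, foods, truth = hn.generate_catalog_and_foods(config)
    return config, catalog, foods, truth


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Small noise-free world where the pipeline must recover truth exactly."""
    config = hn.GeneratorConfig(
        seed=3,
        n_categories=40,
        n_non_nutritive=2,
        density_noise_sigma=0.0,
        outlier_rate=0.0,
        missing_rate=0.0,
        quantity_noise_sigma=0.0,
        purchase_prob=1.0,
        n_strata=4,
        psus_per_stratum=3,
        households_per_psu=5,
    )
    catalog, foods, comp_truth = hn.generate_catalog_and_foods(config)
    table = hn.build_conversion_table(catalog, foods).table
    households, purchases, survey_truth = hn.generate_survey(config, comp_truth)
    return config, table, households, purchases, survey_truth


def quartiles_by_hand(values):
    """Independent quartile oracle: sort, interpolate at position 1 + (n-1)p."""
    v = sorted(x for x in values if not np.isnan(x))
    n = len(v)
    out = []
    for p in (0.25, 0.75):
        pos = (n - 1) * p
        lo = int(np.floor(pos))
        frac = pos - lo
        out.append(v[lo] if lo + 1 >= n else v[lo] + frac * (v[lo + 1] - v[lo]))
    return out[0], out[1]


def flags_by_hand(values):
    """Brute-force Tukey-fence flags for one nutrient's values (NaN never flagged)."""
    arr = np.asarray(values, dtype=float)
    if np.sum(~np.isnan(arr)) == 0 or len(arr) <= 1:
        return np.zeros(len(arr), dtype=bool)
    q1, q3 = quartiles_by_hand(arr)
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(arr), False, (arr < lower) | (arr > upper))
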