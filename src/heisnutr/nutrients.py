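"""Nutrient naming and units shared across the pipeline.

Six nutrients are tracked throughout: energy (kcal), protein (g),
vitamin A (µg retinol activity equivalents, RAE), vitamin C (mg),
iron (mg) and zinc (mg). Conversion-table densities are expressed
per 100 g of edible portion; household availability is expressed
per equivalent adult per day.
"""

from __future__ import annotations

# Canonical nutrient column names, in reporting order.
NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "vita_ug_rae",
    "vitc_mg",
    "fe_mg",
    "zn_mg",
)

#: Human-readable labels with units (densities are per 100 g edible portion).
NUTRIENT_LABELS: dict[str, str] = {
    "energy_kcal": "Energy (kcal)",
    "protein_g": "Protein (g)",
    "vita_ug_rae": "Vitamin A (µg RAE)",
    "vitc_mg": "Vitamin C (mg)",
    "fe_mg": "Iron (mg)",
    "zn_mg": "Zinc (mg)",
}

#: Raw food-composition columns as found in ``food_items.csv``. Vitamin A
#: arrives split into retinol and provitamin-A carotenoids and is collapsed
#: to RAE during standardization.
RAW_NUTRIENT_COLUMNS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "retinol_ug",
    "beta_carotene_ug",
    "other_provitamin_a_ug",
    "vitamin_c_mg",
    "iron_mg",
    "zinc_mg",
)

#: Mapping from raw single-column nutrients to canonical density names.
#: Vitamin A is handled separately (see :func:`heisnutr.table_builder.compute_rae`).
RAW_TO_CANONICAL: dict[str, str] = {
    "energy_kcal": "energy_kcal",
    "protein_g": "protein_g",
    "vitamin_c_mg": "vitc_mg",
    "iron_mg": "fe_mg",
    "zinc_mg": "zn_mg",
}

#: Divisors converting provitamin-A carotenoids to retinol activity
#: equivalents (standard IOM definition): RAE = retinol + beta-carotene/12
#: + other provitamin-A carotenoids/24.
RAE_BETA_CAROTENE_DIVISOR: float = 12.0
RAE_OTHER_CAROTENOID_DIVISOR: float = 24.0

#: Source-table identifiers in priority order (metadata for coverage
#: reports; all paired items contribute to aggregation regardless of source).
SOURCE_PRIORITY: tuple[str, ...] = ("SZ", "MZ", "SMAE", "INCAP", "USDA", "other")
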