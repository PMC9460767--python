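"""Expenditure-category catalog, food-composition records and coverage accounting.

A household expenditure survey classifies food purchases into a fixed set of
expenditure categories (e.g., Mexico's ENIGH uses 245, of which 9 carry no
nutritional value: tobacco, animal feed, food-preparation services, ...).
Food-composition records pair individual foods from published composition
tables to those categories. This module reads and validates both files and
produces the coverage bookkeeping: how many foods and categories each source
table contributed, which nutritive categories remain unpaired, and which are
served by more than one source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .nutrients import RAW_NUTRIENT_COLUMNS

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = ["key", "label", "nutritive"]
FOOD_ITEM_COLUMNS = [
    "food_id",
    "source",
    "category_key",
    "edible_fraction",
    "portion_mass_g",
    *RAW_NUTRIENT_COLUMNS,
]

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    lowered = series.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(_TRUTHY | _FALSY)
    if bad.any():
        raise ValidationError(
            f"column {column!r}: unparseable boolean values "
            f"{sorted(series[bad].astype(str).unique())[:5]}"
        )
    return lowered.isin(_TRUTHY)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_category_catalog(path) -> pd.DataFrame:
    """Read and validate a category catalog CSV (``key,label,nutritive``).

    Returns a DataFrame with columns ``key`` (str), ``label`` (str) and
    ``nutritive`` (bool). Raises :class:`SchemaError` on missing columns and
    :class:`ValidationError` on duplicate keys.
    """
    df = pd.read_csv(path, dtype={"key": str, "label": str})
    _require_columns(df, CATALOG_COLUMNS, "category catalog")
    df = df[CATALOG_COLUMNS].copy()
    df["nutritive"] = _parse_bool(df["nutritive"], "nutritive")
    validate_catalog(df)
    if df.empty:
        logger.warning("category catalog %s is empty", path)
    logger.info(
        "loaded %d categories (%d non-nutritive)", len(df), int((~df["nutritive"]).sum())
    )
    return df.reset_index(drop=True)


def validate_catalog(catalog: pd.DataFrame) -> None:
    """Enforce catalog invariants: required columns and unique keys."""
    _require_columns(catalog, CATALOG_COLUMNS, "category catalog")
    dupes = catalog.loc[catalog["key"].duplicated(), "key"].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate category key(s): {dupes}")
    if catalog["key"].isna().any():
        raise ValidationError("category key must not be missing")


def write_category_catalog(catalog: pd.DataFrame, path) -> None:
    """Write a catalog DataFrame back to CSV (round-trips with the reader)."""
    validate_catalog(catalog)
    catalog.to_csv(path, index=False)


def filter_nutritive(catalog: pd.DataFrame) -> pd.DataFrame:
    """Return only the categories flagged nutritive, preserving order.

    Non-nutritive categories (tobacco, animal feed, ...) are excluded from
    all nutrient analysis; e.g., a 245-category catalog with 9 non-nutritive
    flags leaves 236 analyzable categories.
    """
    return catalog.loc[catalog["nutritive"]].reset_index(drop=True)


def read_food_items(path) -> pd.DataFrame:
    """Read and validate food-composition records.

    Blank nutrient cells become ``NaN`` (explicitly missing — distinct from a
    measured zero). Raises :class:`ValidationError` for negative nutrient
    amounts, edible fractions outside (0, 1], or non-positive portion masses.
    """
    df = pd.read_csv(path, dtype={"food_id": str, "source": str, "category_key": str})
    _require_columns(df, FOOD_ITEM_COLUMNS, "food items")
    df = df[FOOD_ITEM_COLUMNS].copy()
    for col in ("edible_fraction", "portion_mass_g", *RAW_NUTRIENT_COLUMNS):
        df[col] = pd.to_numeric(df[col], errors="raise")
    validate_food_items(df)
    logger.info("loaded %d food items from %d source table(s)", len(df), df["source"].nunique())
    return df.reset_index(drop=True)


def validate_food_items(items: pd.DataFrame) -> None:
    """Enforce food-item invariants (bounds, uniqueness of food_id)."""
    _require_columns(items, FOOD_ITEM_COLUMNS, "food items")
    dupes = items.loc[items["food_id"].duplicated(), "food_id"].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate food_id(s): {dupes}")
    bad_ef = ~((items["edible_fraction"] > 0) & (items["edible_fraction"] <= 1))
    if bad_ef.any():
        raise ValidationError(
            "edible_fraction must lie in (0, 1]; offending food_id(s): "
            f"{items.loc[bad_ef, 'food_id'].tolist()[:5]}"
        )
    if (items["portion_mass_g"] <= 0).any():
        raise ValidationError(
            "portion_mass_g must be > 0; offending food_id(s): "
            f"{items.loc[items['portion_mass_g'] <= 0, 'food_id'].tolist()[:5]}"
        )
    for col in RAW_NUTRIENT_COLUMNS:
        neg = items[col].notna() & (items[col] < 0)
        if neg.any():
            raise ValidationError(
                f"negative {col} for food_id(s): {items.loc[neg, 'food_id'].tolist()[:5]}"
            )


def write_food_items(items: pd.DataFrame, path) -> None:
    """Write food items to CSV (round-trips with the reader)."""
    validate_food_items(items)
    items.to_csv(path, index=False)


@dataclass
class CoverageReport:
    """Bookkeeping of how the composition sources cover the catalog.

    ``total_categories_paired`` counts each category once even when several
    sources pair foods into it, so it equals the size of the union of the
    per-source category sets and may be smaller than the column sum of
    ``per_source['n_categories']``.
    """

    per_source: pd.DataFrame  # index: source; columns: n_foods, n_categories
    total_foods: int
    total_categories_paired: int
    n_nutritive_categories: int
    empty_nutritive_categories: list[str] = field(default_factory=list)
    multi_source_categories: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Serialize the per-source counts plus a totals row."""
        out = self.per_source.copy()
        out.loc["All pairings"] = [self.total_foods, self.total_categories_paired]
        return out.reset_index(names="source")


def coverage_report(catalog: pd.DataFrame, items: pd.DataFrame) -> CoverageReport:
    """Account for source-by-source pairing coverage of the nutritive catalog.

    Raises :class:`ValidationError` if any item references an unknown or
    non-nutritive category key.
    """
    validate_catalog(catalog)
    nutritive = filter_nutritive(catalog)
    nutritive_keys = set(nutritive["key"])
    all_keys = set(catalog["key"])

    unknown = sorted(set(items["category_key"]) - all_keys)
    if unknown:
        raise ValidationError(f"food item(s) reference unknown category key(s): {unknown[:10]}")
    non_nutritive_hits = sorted(set(items["category_key"]) - nutritive_keys)
    if non_nutritive_hits:
        raise ValidationError(
            f"food item(s) paired to non-nutritive category key(s): {non_nutritive_hits[:10]}"
        )

    if items.empty:
        per_source = pd.DataFrame(columns=["n_foods", "n_categories"], dtype=int)
        per_source.index.name = "source"
        return CoverageReport(
            per_source=per_source,
            total_foods=0,
            total_categories_paired=0,
            n_nutritive_categories=len(nutritive_keys),
            empty_nutritive_categories=sorted(nutritive_keys),
            multi_source_categories=[],
        )

    per_source = (
        items.groupby("source")
        .agg(n_foods=("food_id", "size"), n_categories=("category_key", "nunique"))
        .astype(int)
    )
    paired = set(items["category_key"])
    sources_per_category = items.groupby("category_key")["source"].nunique()
    multi = sorted(sources_per_category.index[sources_per_category > 1])
    empty = sorted(nutritive_keys - paired)
    if empty:
        logger.warning("%d nutritive categories have no paired food", len(empty))
    return CoverageReport(
        per_source=per_source,
        total_foods=int(len(items)),
        total_categories_paired=int(len(paired)),
        n_nutritive_categories=len(nutritive_keys),
        empty_nutritive_categories=empty,
        multi_source_categories=multi,
    )
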