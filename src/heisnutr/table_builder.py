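"""Build the category-level nutrient conversion table.

Pipeline for one expenditure category: (1) standardize every paired food to
densities per 100 g of edible portion, collapsing retinol and provitamin-A
carotenoids into retinol activity equivalents (RAE); (2) per nutrient, flag
values lying strictly outside Tukey's fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR];
(3) eliminate items flagged in two or more nutrients; (4) aggregate the
surviving, unflagged values with the mean (or, alternatively, the median).

Fences are computed once from all items in a category; they are not
recomputed after drops. Values exactly on a fence are not outliers (the
interval is closed). Quartiles use linear interpolation between order
statistics at positions 1 + (n−1)p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import filter_nutritive, validate_catalog, validate_food_items
from .errors import DegenerateDataError, ValidationError
from .nutrients import (
    NUTRIENTS,
    RAE_BETA_CAROTENE_DIVISOR,
    RAE_OTHER_CAROTENOID_DIVISOR,
    RAW_TO_CANONICAL,
)

logger = logging.getLogger(__name__)

STANDARDIZED_COLUMNS = ["food_id", "source", "category_key", "edible_fraction", *NUTRIENTS]

#: Conversion-table CSV columns (densities carry a ``_100g`` suffix on disk).
TABLE_DENSITY_COLUMNS = {n: f"{n}_100g" for n in NUTRIENTS}


def compute_rae(
    retinol_ug,
    beta_carotene_ug,
    other_provitamin_a_ug,
    *,
    beta_divisor: float = RAE_BETA_CAROTENE_DIVISOR,
    other_divisor: float = RAE_OTHER_CAROTENOID_DIVISOR,
):
    """Vitamin A in µg retinol activity equivalents.

    RAE = retinol + beta-carotene/12 + other provitamin-A carotenoids/24
    (standard IOM divisors, configurable). Missing components contribute
    nothing as long as at least one component is present; if all three are
    missing the result is missing. Accepts scalars or aligned array-likes.

    Raises
    ------
    ValidationError
        If any present input is negative.
    """
    r = np.asarray(retinol_ug, dtype=float)
    b = np.asarray(beta_carotene_ug, dtype=float)
    o = np.asarray(other_provitamin_a_ug, dtype=float)
    for name, arr in (("retinol_ug", r), ("beta_carotene_ug", b), ("other_provitamin_a_ug", o)):
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValidationError(f"negative {name} in RAE computation")
    all_missing = np.isnan(r) & np.isnan(b) & np.isnan(o)
    rae = np.nan_to_num(r) + np.nan_to_num(b) / beta_divisor + np.nan_to_num(o) / other_divisor
    rae = np.where(all_missing, np.nan, rae)
    if rae.ndim == 0:
        return float(rae)
    return rae


def standardize_items(items: pd.DataFrame) -> pd.DataFrame:
    """Standardize raw food-composition records to densities per 100 g edible portion.

    Each present nutrient amount is scaled by ``100 / portion_mass_g``;
    vitamin A is collapsed to RAE before scaling. Missing amounts stay
    missing. The result is invariant under rescaling of the source portion
    (doubling ``portion_mass_g`` and all amounts changes nothing).
    """
    validate_food_items(items)
    out = items[["food_id", "source", "category_key", "edible_fraction"]].copy()
    scale = 100.0 / items["portion_mass_g"].to_numpy(dtype=float)
    rae = compute_rae(
        items["retinol_ug"], items["beta_carotene_ug"], items["other_provitamin_a_ug"]
    )
    out["vita_ug_rae"] = np.asarray(rae) * scale
    for raw, canon in RAW_TO_CANONICAL.items():
        out[canon] = items[raw].to_numpy(dtype=float) * scale
    return out[STANDARDIZED_COLUMNS].reset_index(drop=True)


def standardize_to_100g(item: pd.Series) -> pd.Series:
    """Standardize a single raw food-composition record (row-level convenience)."""
    return standardize_items(item.to_frame().T).iloc[0]


@dataclass(frozen=True)
class Fence:
    """Tukey's fences for one nutrient within one category."""

    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr

    def contains(self, value) -> np.ndarray:
        """True where ``value`` lies inside the closed interval [lower, upper].

        The interval is closed — a value exactly on a fence is not an
        outlier — and the comparison carries a relative numerical guard
        (1e-9 of the fence scale) so that values equal to a fence up to
        floating-point round-off stay inside; degenerate zero-width fences
        otherwise flag ulp-level jitter.
        """
        v = np.asarray(value, dtype=float)
        tol = 1e-9 * max(abs(self.lower), abs(self.upper), 1e-300)
        return (v >= self.lower - tol) & (v <= self.upper + tol)


def tukey_fence(values) -> Fence:
    """Compute Tukey's fences from the non-missing values of one nutrient.

    Quartiles are obtained by linear interpolation on the sorted values
    (positions 1 + (n−1)p). Raises :class:`DegenerateDataError` when no
    non-missing value is available.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise DegenerateDataError("cannot build a fence from all-missing values")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    return Fence(q1=float(q1), q3=float(q3))


def flag_outliers(std_items: pd.DataFrame) -> pd.DataFrame:
    """Per-item, per-nutrient outlier flags for one category's standardized items.

    A value is flagged iff it falls strictly outside its nutrient's fences.
    Missing values are never flagged, and a single-item category yields no
    flags (its fences collapse onto the lone value).
    """
    flags = pd.DataFrame(False, index=std_items.index, columns=list(NUTRIENTS))
    if len(std_items) <= 1:
        return flags
    for nutrient in NUTRIENTS:
        col = std_items[nutrient]
        present = col.notna()
        if not present.any():
            continue
        fence = tukey_fence(col)
        inside = fence.contains(col[present])
        flags.loc[present[present].index, nutrient] = ~inside
    return flags


def drop_multi_outlier_items(
    std_items: pd.DataFrame, flags: pd.DataFrame, threshold: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eliminate items whose flagged-nutrient count reaches ``threshold``.

    Returns the retained items and a drop log with columns
    ``food_id, category_key, flagged_nutrients``. Items flagged in fewer
    nutrients are retained (their flagged values are still excluded later,
    during aggregation). Raises :class:`DegenerateDataError` if a category
    loses every item.
    """
    n_flags = flags.sum(axis=1)
    dropped_mask = n_flags >= threshold
    drop_log = pd.DataFrame(
        {
            "food_id": std_items.loc[dropped_mask, "food_id"].to_numpy(),
            "category_key": std_items.loc[dropped_mask, "category_key"].to_numpy(),
            "flagged_nutrients": [
                ",".join(flags.columns[row]) for _, row in flags.loc[dropped_mask].iterrows()
            ],
        }
    )
    retained = std_items.loc[~dropped_mask]
    if len(std_items) and retained.empty:
        keys = std_items["category_key"].unique().tolist()
        raise DegenerateDataError(f"all items dropped in category {keys}")
    return retained, drop_log


def aggregate_category(
    retained: pd.DataFrame, flags: pd.DataFrame, method: str = "mean"
) -> pd.Series:
    """Aggregate one category's retained items into a nutrient profile.

    Per nutrient, the aggregate (mean or median) runs over the retained
    items' non-missing, non-flagged values. The edible fraction is aggregated
    with the same method. A nutrient with no usable value is emitted missing
    with a warning (the category needs re-pairing from further sources).
    """
    if method not in ("mean", "median"):
        raise ValidationError(f"aggregation method must be 'mean' or 'median', got {method!r}")
    if retained.empty:
        raise DegenerateDataError("cannot aggregate an empty category")
    agg = np.mean if method == "mean" else np.median
    key = retained["category_key"].iloc[0]
    profile: dict[str, object] = {"category_key": key}
    profile["edible_fraction"] = float(agg(retained["edible_fraction"].to_numpy(dtype=float)))
    for nutrient in NUTRIENTS:
        values = retained[nutrient]
        usable = values.notna() & ~flags.loc[retained.index, nutrient]
        if not usable.any():
            logger.warning(
                "category %s: no usable %s value; density emitted missing "
                "(category flagged for re-pairing)",
                key,
                nutrient,
            )
            profile[nutrient] = np.nan
        else:
            profile[nutrient] = float(agg(values[usable].to_numpy(dtype=float)))
    profile["n_items_retained"] = int(len(retained))
    profile["method"] = method
    return pd.Series(profile)


@dataclass
class ConversionTableResult:
    """Output of :func:`build_conversion_table`."""

    table: pd.DataFrame
    drop_log: pd.DataFrame
    empty_categories: list[str] = field(default_factory=list)
    missing_densities: list[tuple[str, str]] = field(default_factory=list)


def build_conversion_table(
    catalog: pd.DataFrame,
    items: pd.DataFrame,
    method: str = "mean",
    outlier_threshold: int = 2,
) -> ConversionTableResult:
    """Build the full conversion table: one nutrient profile per covered category.

    Deterministic given its inputs. Nutritive categories with no paired item
    are reported collectively in ``empty_categories`` (they trigger another
    pairing iteration from additional composition sources, not an error).
    """
    validate_catalog(catalog)
    std = standardize_items(items)
    nutritive = filter_nutritive(catalog)
    covered = set(std["category_key"])
    empty = sorted(set(nutritive["key"]) - covered)

    profiles: list[pd.Series] = []
    drop_logs: list[pd.DataFrame] = []
    missing: list[tuple[str, str]] = []
    for key, group in std.groupby("category_key", sort=True):
        flags = flag_outliers(group)
        retained, dropped = drop_multi_outlier_items(group, flags, threshold=outlier_threshold)
        if not dropped.empty:
            drop_logs.append(dropped)
        profile = aggregate_category(retained, flags, method=method)
        profile["n_items_dropped"] = int(len(group) - len(retained))
        missing.extend((str(key), n) for n in NUTRIENTS if pd.isna(profile[n]))
        profiles.append(profile)

    table = pd.DataFrame(profiles).reset_index(drop=True)
    column_order = [
        "category_key",
        "edible_fraction",
        *NUTRIENTS,
        "n_items_retained",
        "n_items_dropped",
        "method",
    ]
    table = table[column_order]
    table["n_items_retained"] = table["n_items_retained"].astype(int)
    table["n_items_dropped"] = table["n_items_dropped"].astype(int)
    drop_log = (
        pd.concat(drop_logs, ignore_index=True)
        if drop_logs
        else pd.DataFrame(columns=["food_id", "category_key", "flagged_nutrients"])
    )
    if empty:
        logger.warning("%d nutritive categories have no paired items: %s", len(empty), empty[:10])
    return ConversionTableResult(
        table=table, drop_log=drop_log, empty_categories=empty, missing_densities=missing
    )


def write_conversion_table(table: pd.DataFrame, path) -> None:
    """Write a conversion table to CSV with ``_100g``-suffixed density columns."""
    out = table.rename(columns=TABLE_DENSITY_COLUMNS)
    out.to_csv(path, index=False)


def read_conversion_table(path) -> pd.DataFrame:
    """Read a conversion table written by :func:`write_conversion_table`."""
    df = pd.read_csv(path, dtype={"category_key": str})
    df = df.rename(columns={v: k for k, v in TABLE_DENSITY_COLUMNS.items()})
    expected = {"category_key", "edible_fraction", *NUTRIENTS}
    missing = expected - set(df.columns)
    if missing:
        raise ValidationError(f"conversion table missing column(s): {sorted(missing)}")
    return df
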