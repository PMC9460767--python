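"""Convert purchase microdata into household-level daily nutrient availability.

For each food-at-home purchase, nutrients for the reference period are
``quantity_g × edible_fraction × density / 100`` (densities are per 100 g of
edible portion). Purchases are summed per household, divided by the length of
the reference period (typically 7 days) and by the household's number of
equivalent adults. Food-away-from-home (FAFH) records carry expenditure only
— no quantity — and are excluded from nutrient conversion by design; they are
counted and surface in the expenditure diagnostics instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import CoverageError, SchemaError, ValidationError
from .nutrients import NUTRIENTS

logger = logging.getLogger(__name__)

PURCHASE_COLUMNS = ["household_id", "category_key", "quantity_g", "expenditure", "is_fafh"]
HOUSEHOLD_COLUMNS = ["household_id", "stratum", "psu", "weight", "income", "member_ages"]

DEFAULT_REFERENCE_DAYS = 7


@dataclass(frozen=True)
class AgeBand:
    """One band of an equivalence scale: applies to ages < ``max_age`` (None = open-ended)."""

    max_age: float | None
    weight: float


@dataclass(frozen=True)
class EquivalenceScale:
    """Per-member weights converting household composition to equivalent adults.

    Bands partition [0, ∞) by age; the reference adult has weight 1.0.
    The official scales used with real surveys (e.g., CONEVAL's for Mexico)
    are supplied by the user as config; the default here is illustrative.
    """

    bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValidationError("equivalence scale needs at least one band")
        if self.bands[-1].max_age is not None:
            raise ValidationError("last equivalence-scale band must be open-ended")
        cuts = [b.max_age for b in self.bands[:-1]]
        if any(c is None for c in cuts) or list(cuts) != sorted(cuts):  # type: ignore[arg-type]
            raise ValidationError("equivalence-scale bands must have increasing max_age")
        if any(b.weight <= 0 for b in self.bands):
            raise ValidationError("equivalence-scale weights must be positive")

    def weight_for(self, age: float) -> float:
        if age < 0:
            raise ValidationError(f"member age must be non-negative, got {age}")
        for band in self.bands:
            if band.max_age is None or age < band.max_age:
                return band.weight
        raise AssertionError("unreachable: last band is open-ended")

    @classmethod
    def from_dict(cls, spec: dict) -> "EquivalenceScale":
        bands = tuple(
            AgeBand(max_age=b.get("max_age"), weight=float(b["weight"])) for b in spec["bands"]
        )
        return cls(bands=bands)

    @classmethod
    def from_yaml(cls, path) -> "EquivalenceScale":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {"bands": [{"max_age": b.max_age, "weight": b.weight} for b in self.bands]}


#: Illustrative default scale (NOT an official one): children under 5 count
#: 0.70 of an adult, ages 5–13 count 0.80, everyone 14+ counts 1.00.
DEFAULT_SCALE = EquivalenceScale(
    bands=(AgeBand(5, 0.70), AgeBand(14, 0.80), AgeBand(None, 1.00))
)


def equivalent_adults(member_ages, scale: EquivalenceScale = DEFAULT_SCALE) -> float:
    """Sum of per-member equivalence weights for one household."""
    ages = list(member_ages)
    if not ages:
        raise ValidationError("household must have at least one member")
    return float(sum(scale.weight_for(a) for a in ages))


def _parse_ages(serialized: str) -> list[float]:
    parts = [p for p in str(serialized).split("|") if p != ""]
    if not parts:
        raise ValidationError(f"empty member_ages field: {serialized!r}")
    return [float(p) for p in parts]


def read_households(path, scale: EquivalenceScale = DEFAULT_SCALE) -> pd.DataFrame:
    """Read the household roster CSV and derive member counts and equivalent adults.

    Expects ``household_id,stratum,psu,weight,income,member_ages`` with ages
    pipe-delimited (e.g., ``34|31|6``). Adds ``n_members`` and ``equivalent_adults``.
    """
    df = pd.read_csv(path, dtype={"household_id": str, "stratum": str, "psu": str})
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"households: missing column(s) {missing}")
    df = df.copy()
    df["member_ages"] = df["member_ages"].map(_parse_ages)
    return derive_household_fields(df, scale)


def derive_household_fields(
    households: pd.DataFrame, scale: EquivalenceScale = DEFAULT_SCALE
) -> pd.DataFrame:
    """Validate the roster and (re)compute ``n_members`` and ``equivalent_adults``."""
    df = households.copy()
    if df["household_id"].duplicated().any():
        dupes = df.loc[df["household_id"].duplicated(), "household_id"].tolist()
        raise ValidationError(f"duplicate household_id(s): {dupes[:5]}")
    if (pd.to_numeric(df["weight"]) <= 0).any():
        raise ValidationError("expansion factors (weight) must be positive")
    df["n_members"] = df["member_ages"].map(len)
    df["equivalent_adults"] = df["member_ages"].map(lambda ages: equivalent_adults(ages, scale))
    return df


def write_households(households: pd.DataFrame, path) -> None:
    out = households[HOUSEHOLD_COLUMNS].copy()
    out["member_ages"] = out["member_ages"].map(
        lambda ages: "|".join(format(a, "g") for a in ages)
    )
    out.to_csv(path, index=False)


def read_purchases(path) -> pd.DataFrame:
    """Read purchase microdata (``household_id,category_key,quantity_g,expenditure,is_fafh``)."""
    df = pd.read_csv(path, dtype={"household_id": str, "category_key": str})
    missing = [c for c in PURCHASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"purchases: missing column(s) {missing}")
    df = df.copy()
    if df["is_fafh"].dtype != bool:
        df["is_fafh"] = (
            df["is_fafh"].astype(str).str.strip().str.lower().isin({"true", "1", "yes", "t"})
        )
    validate_purchases(df)
    return df.reset_index(drop=True)


def validate_purchases(purchases: pd.DataFrame) -> None:
    fafh = purchases["is_fafh"]
    if purchases.loc[fafh, "quantity_g"].notna().any():
        raise ValidationError("FAFH records must not carry a quantity")
    at_home_qty = purchases.loc[~fafh, "quantity_g"]
    if (at_home_qty.dropna() < 0).any():
        raise ValidationError("quantity_g must be >= 0")
    if (pd.to_numeric(purchases["expenditure"]).dropna() < 0).any():
        raise ValidationError("expenditure must be >= 0")


def write_purchases(purchases: pd.DataFrame, path) -> None:
    purchases[PURCHASE_COLUMNS].to_csv(path, index=False)


def purchase_to_nutrients(purchase: pd.Series, profile: pd.Series) -> pd.Series:
    """Nutrients acquired by a single purchase over the reference period.

    ``quantity_g × edible_fraction × density / 100`` per nutrient. FAFH
    records are excluded from conversion by design and raise here.
    """
    if bool(purchase.get("is_fafh", False)):
        raise ValidationError("FAFH records carry no quantity and cannot be converted")
    qty = float(purchase["quantity_g"])
    factor = qty * float(profile["edible_fraction"]) / 100.0
    return pd.Series({n: factor * float(profile[n]) for n in NUTRIENTS})


def household_daily_availability(
    purchases: pd.DataFrame,
    table: pd.DataFrame,
    households: pd.DataFrame,
    reference_days: int = DEFAULT_REFERENCE_DAYS,
) -> pd.DataFrame:
    """Daily per-equivalent-adult nutrient availability for every household.

    Sums period nutrients over each household's food-at-home purchases, then
    divides by ``reference_days`` and by the household's equivalent adults.
    Households with no food-at-home purchases are retained with zero
    availability (dropping them would bias population means upward).

    Parameters
    ----------
    purchases : DataFrame
        Purchase microdata; FAFH rows are ignored (their count is logged).
    table : DataFrame
        Conversion table with ``category_key``, ``edible_fraction`` and the
        six nutrient densities per 100 g edible portion.
    households : DataFrame
        Roster with derived ``equivalent_adults`` (see :func:`read_households`).

    Raises
    ------
    CoverageError
        If a food-at-home purchase references a category absent from the table.
    """
    if reference_days <= 0:
        raise ValidationError("reference_days must be positive")
    at_home = purchases.loc[~purchases["is_fafh"]].copy()
    n_fafh = int(purchases["is_fafh"].sum())
    if n_fafh:
        logger.info("ignoring %d FAFH record(s) in nutrient conversion", n_fafh)

    uncovered = sorted(set(at_home["category_key"]) - set(table["category_key"]))
    if uncovered:
        raise CoverageError(f"purchases reference uncovered category key(s): {uncovered[:10]}")

    merged = at_home.merge(
        table[["category_key", "edible_fraction", *NUTRIENTS]], on="category_key", how="left"
    )
    factor = merged["quantity_g"].to_numpy(dtype=float) * merged["edible_fraction"].to_numpy(
        dtype=float
    ) / 100.0
    for n in NUTRIENTS:
        merged[n] = factor * merged[n].to_numpy(dtype=float)
    period_totals = merged.groupby("household_id")[list(NUTRIENTS)].sum()

    out = households[["household_id", "equivalent_adults"]].copy()
    out = out.merge(period_totals, left_on="household_id", right_index=True, how="left")
    out[list(NUTRIENTS)] = out[list(NUTRIENTS)].fillna(0.0)
    denom = reference_days * out["equivalent_adults"].to_numpy(dtype=float)
    for n in NUTRIENTS:
        out[n] = out[n].to_numpy(dtype=float) / denom
    return out.drop(columns=["equivalent_adults"])


def deflate(expenditure, year_index: float, base_index: float):
    """Deflate nominal expenditure to constant base-year prices via CPI indices."""
    if year_index <= 0 or base_index <= 0:
        raise ValidationError("CPI indices must be positive")
    return np.asarray(expenditure, dtype=float) * (base_index / year_index)
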