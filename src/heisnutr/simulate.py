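"""Seeded generator of HEIS-like fixtures with known ground truth.

Emulates the structure of a Mexican-style income-expenditure survey: an
expenditure-category catalog (245 categories, 9 of them non-nutritive by
default), multi-source food-composition records with optional injected
contamination, and a stratified two-stage household frame with expansion
factors, a log-normal income distribution, an income gradient in the
category mix of purchases, and food-away-from-home (FAFH) records that carry
expenditure only.

Every draw flows from a single integer seed; the generator also returns
truth records (true category densities, per-household expected availability,
true population means and quintile gradients, FAFH participation and share)
so downstream estimates can be checked against known values.

The income gradient works through the category mix: each category is
"dominated" by one nutrient (its density for that nutrient is drawn from a
high range, the rest from low ranges) and richer households buy more of
categories dominated by nutrients with positive gradient coefficients —
the mechanism behind observed income gradients in protein and vitamins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .conversion import DEFAULT_SCALE, EquivalenceScale, equivalent_adults
from .nutrients import NUTRIENTS, SOURCE_PRIORITY
from .survey import assign_income_quintiles

# per-100 g density ranges (log-uniform draws): low = background, high = the
# category's dominant nutrient
_DENSITY_RANGES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "energy_kcal": ((20.0, 150.0), (250.0, 600.0)),
    "protein_g": ((1.0, 5.0), (10.0, 30.0)),
    "vita_ug_rae": ((5.0, 50.0), (200.0, 900.0)),
    "vitc_mg": ((0.5, 8.0), (20.0, 80.0)),
    "fe_mg": ((0.3, 2.0), (3.0, 10.0)),
    "zn_mg": ((0.2, 1.5), (3.0, 9.0)),
}

_SOURCE_PROBS = (0.78, 0.12, 0.04, 0.03, 0.02, 0.01)


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic survey, with HEIS-realistic defaults."""

    seed: int
    # catalog / composition
    n_categories: int = 245
    n_non_nutritive: int = 9
    items_per_category: tuple[int, int] = (6, 12)
    density_noise_sigma: float = 0.01  # log-normal sd of item densities around truth
    missing_rate: float = 0.02  # probability a nutrient value is missing on an item
    outlier_rate: float = 0.05  # probability an item is contaminated
    outlier_magnitude: float = 10.0  # contaminated values are multiplied by this
    # survey frame
    n_strata: int = 10
    psus_per_stratum: int = 4
    households_per_psu: int = 10
    weight_range: tuple[float, float] = (50.0, 500.0)
    income_log_mean: float = 9.0
    income_log_sigma: float = 0.7
    mean_extra_members: float = 2.2  # household size = 1 + Poisson(this), capped at 9
    # purchases
    purchase_prob: float = 0.15  # probability a household buys a given category
    base_quantity_range: tuple[float, float] = (80.0, 800.0)  # g per category per week
    quantity_noise_sigma: float = 0.25
    price_per_g_range: tuple[float, float] = (0.02, 0.2)
    nutrient_gradients: dict[str, float] = Field(
        default_factory=lambda: {
            "energy_kcal": 0.03,
            "protein_g": 0.11,
            "vita_ug_rae": 0.19,
            "vitc_mg": 0.31,
            "fe_mg": 0.02,
            "zn_mg": 0.03,
        }
    )
    fafh_participation: float = 0.6
    # share of total food expenditure among participating households;
    # Beta(2.5, 3.5) has mean ~0.42, giving a population-level share ~25%
    fafh_share_alpha: float = 2.5
    fafh_share_beta: float = 3.5
    reference_days: int = 7

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n_non_nutritive >= self.n_categories:
            raise ValueError("n_non_nutritive must be smaller than n_categories")
        lo, hi = self.items_per_category
        if lo < 1 or hi < lo:
            raise ValueError("items_per_category must be a valid positive range")
        for rate in (self.outlier_rate, self.missing_rate, self.purchase_prob,
                     self.fafh_participation):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.n_strata, self.psus_per_stratum, self.households_per_psu) < 1:
            raise ValueError("survey frame counts must be positive")
        return self


@dataclass
class CompositionTruth:
    """True (pre-noise, pre-contamination) category properties."""

    densities: pd.DataFrame  # index category_key; edible_fraction + six densities
    income_elasticity: pd.Series  # per-category elasticity of purchases w.r.t. income
    contaminated_food_ids: list[str] = field(default_factory=list)


@dataclass
class SurveyTruth:
    """Exact expectations implied by the generated microdata."""

    expected_availability: pd.DataFrame  # household_id + six nutrients
    population_mean: dict[str, float]  # weighted mean of expected availability
    quintile_ratio: dict[str, float]  # quintile V over quintile I expected means
    fafh_participation: float
    fafh_mean_share: float  # population-level mean share (zeros included)


def generate_catalog_and_foods(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CompositionTruth]:
    """Generate the category catalog, food-composition records and their truth."""
    rng = np.random.default_rng(config.seed)
    n, n_nn = config.n_categories, config.n_non_nutritive
    keys = [f"A{i:03d}" for i in range(1, n + 1)]
    non_nutritive_idx = set(rng.choice(n, size=n_nn, replace=False).tolist())
    catalog = pd.DataFrame(
        {
            "key": keys,
            "label": [
                f"Non-food category {i + 1}" if i in non_nutritive_idx else f"Food category {i + 1}"
                for i in range(n)
            ],
            "nutritive": [i not in non_nutritive_idx for i in range(n)],
        }
    )

    nutritive_keys = [k for i, k in enumerate(keys) if i not in non_nutritive_idx]
    n_cat = len(nutritive_keys)
    dominant = rng.integers(0, len(NUTRIENTS), size=n_cat)
    densities = np.empty((n_cat, len(NUTRIENTS)))
    for j, nutrient in enumerate(NUTRIENTS):
        low, high = _DENSITY_RANGES[nutrient]
        lo_draw = np.exp(rng.uniform(np.log(low[0]), np.log(low[1]), size=n_cat))
        hi_draw = np.exp(rng.uniform(np.log(high[0]), np.log(high[1]), size=n_cat))
        densities[:, j] = np.where(dominant == j, hi_draw, lo_draw)
    edible = rng.uniform(0.6, 1.0, size=n_cat)
    truth_df = pd.DataFrame(densities, columns=list(NUTRIENTS), index=nutritive_keys)
    truth_df.insert(0, "edible_fraction", edible)
    truth_df.index.name = "category_key"
    gradients = np.array([config.nutrient_gradients.get(nut, 0.0) for nut in NUTRIENTS])
    elasticity = pd.Series(gradients[dominant], index=nutritive_keys, name="income_elasticity")

    # one dominant source per category, a handful of categories multi-sourced
    cat_source = rng.choice(len(SOURCE_PRIORITY), size=n_cat, p=_SOURCE_PROBS)
    rows: list[dict] = []
    contaminated: list[str] = []
    sigma = config.density_noise_sigma
    food_counter = 0
    for c, key in enumerate(nutritive_keys):
        n_items = int(rng.integers(config.items_per_category[0], config.items_per_category[1] + 1))
        second_source = rng.random() < 0.01 and n_items >= 2
        # Collision-free contamination: at most one planted outlier per
        # category-nutrient cell (and at most two contaminated items per
        # category), because overlapping outliers can mask each other by
        # inflating the fence itself — the generator plants errors the
        # fence rule is designed to catch.
        n_contam = min(int(rng.binomial(n_items, config.outlier_rate)), 2)
        contam_nutrients: dict[int, set[int]] = {}
        if n_contam:
            chosen = rng.choice(n_items, size=n_contam, replace=False)
            free = list(range(len(NUTRIENTS)))
            for idx in chosen:
                k = min(int(rng.integers(2, 4)), len(free))
                pick = rng.choice(free, size=k, replace=False)
                contam_nutrients[int(idx)] = set(int(j) for j in pick)
                free = [j for j in free if j not in contam_nutrients[int(idx)]]
        for i in range(n_items):
            food_counter += 1
            food_id = f"F{food_counter:05d}"
            source_idx = cat_source[c]
            if second_source and i == n_items - 1:
                source_idx = (source_idx + 1) % len(SOURCE_PRIORITY)
            portion = float(rng.uniform(30.0, 500.0))
            if sigma > 0:
                noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=len(NUTRIENTS)))
            else:
                noise = np.ones(len(NUTRIENTS))
            dens = densities[c] * noise
            missing = np.zeros(len(NUTRIENTS), dtype=bool)
            if config.missing_rate > 0:
                # energy is always reported in composition tables
                missing[1:] = rng.random(len(NUTRIENTS) - 1) < config.missing_rate
            if i in contam_nutrients:
                hit = sorted(contam_nutrients[i])
                missing[hit] = False  # a planted outlier must stay visible
                dens = dens.copy()
                dens[hit] *= config.outlier_magnitude
                contaminated.append(food_id)
            amounts = dens * portion / 100.0
            by_name = dict(zip(NUTRIENTS, amounts))
            # split vitamin A RAE into retinol + provitamin-A carotenoids
            r = float(rng.uniform(0.2, 0.9))
            rae = by_name.pop("vita_ug_rae")
            row = {
                "food_id": food_id,
                "source": SOURCE_PRIORITY[source_idx],
                "category_key": key,
                "edible_fraction": float(edible[c]),
                "portion_mass_g": portion,
                "energy_kcal": by_name["energy_kcal"],
                "protein_g": by_name["protein_g"],
                "retinol_ug": r * rae,
                "beta_carotene_ug": (1.0 - r) * 0.7 * rae * 12.0,
                "other_provitamin_a_ug": (1.0 - r) * 0.3 * rae * 24.0,
                "vitamin_c_mg": by_name["vitc_mg"],
                "iron_mg": by_name["fe_mg"],
                "zinc_mg": by_name["zn_mg"],
            }
            raw_by_canonical = {
                "protein_g": ("protein_g",),
                "vita_ug_rae": ("retinol_ug", "beta_carotene_ug", "other_provitamin_a_ug"),
                "vitc_mg": ("vitamin_c_mg",),
                "fe_mg": ("iron_mg",),
                "zn_mg": ("zinc_mg",),
            }
            for j, canonical in enumerate(NUTRIENTS):
                if missing[j]:
                    for raw_col in raw_by_canonical[canonical]:
                        row[raw_col] = np.nan
            rows.append(row)
    foods = pd.DataFrame(rows)
    truth = CompositionTruth(
        densities=truth_df, income_elasticity=elasticity, contaminated_food_ids=contaminated
    )
    return catalog, foods, truth


def generate_survey(
    config: GeneratorConfig,
    composition: CompositionTruth,
    scale: EquivalenceScale = DEFAULT_SCALE,
) -> tuple[pd.DataFrame, pd.DataFrame, SurveyTruth]:
    """Generate the household frame and purchase microdata for one survey year.

    Returns the roster (with derived ``n_members`` / ``equivalent_adults``),
    the purchases (FAFH rows carry expenditure only, under the reserved
    category key ``"FAFH"``), and the exact expectations they imply.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_hh = config.n_strata * config.psus_per_stratum * config.households_per_psu

    strata, psus = [], []
    for s in range(config.n_strata):
        for p in range(config.psus_per_stratum):
            strata.extend([f"S{s + 1:02d}"] * config.households_per_psu)
            psus.extend([f"S{s + 1:02d}-P{p + 1}"] * config.households_per_psu)
    weights = rng.uniform(*config.weight_range, size=n_hh)
    income = np.exp(rng.normal(config.income_log_mean, config.income_log_sigma, size=n_hh))
    sizes = np.minimum(1 + rng.poisson(config.mean_extra_members, size=n_hh), 9)
    ages = [
        [float(rng.integers(18, 70))] + [float(a) for a in rng.integers(0, 80, size=k - 1)]
        for k in sizes
    ]
    households = pd.DataFrame(
        {
            "household_id": [f"H{i + 1:05d}" for i in range(n_hh)],
            "stratum": strata,
            "psu": psus,
            "weight": weights,
            "income": income,
            "member_ages": ages,
        }
    )
    households["n_members"] = households["member_ages"].map(len)
    households["equivalent_adults"] = households["member_ages"].map(
        lambda a: equivalent_adults(a, scale)
    )

    cats = composition.densities.index.to_numpy()
    n_cat = len(cats)
    base = rng.uniform(*config.base_quantity_range, size=n_cat)
    price = rng.uniform(*config.price_per_g_range, size=n_cat)
    gamma = composition.income_elasticity.to_numpy()

    # purchases scale with household size (equivalent adults); the income
    # gradient acts on income per equivalent adult, relative to its median
    ae = households["equivalent_adults"].to_numpy()
    income_pae = income / ae
    ref_income = float(np.median(income_pae))
    mix = (income_pae[:, None] / ref_income) ** gamma[None, :]
    expected_qty = ae[:, None] * base[None, :] * mix  # E[quantity | purchased]

    buys = rng.random((n_hh, n_cat)) < config.purchase_prob
    sig = config.quantity_noise_sigma
    if sig > 0:
        qty = expected_qty * np.exp(rng.normal(-sig**2 / 2.0, sig, size=(n_hh, n_cat)))
    else:
        qty = expected_qty.copy()
    qty = np.where(buys, qty, 0.0)

    hh_idx, cat_idx = np.nonzero(buys)
    purchases = pd.DataFrame(
        {
            "household_id": households["household_id"].to_numpy()[hh_idx],
            "category_key": cats[cat_idx],
            "quantity_g": qty[hh_idx, cat_idx],
            "expenditure": qty[hh_idx, cat_idx] * price[cat_idx],
            "is_fafh": False,
        }
    )

    # FAFH: expenditure only, derived from the household's at-home food bill
    at_home_exp = pd.Series(
        purchases.groupby("household_id")["expenditure"].sum(),
    ).reindex(households["household_id"], fill_value=0.0)
    participates = rng.random(n_hh) < config.fafh_participation
    share = rng.beta(config.fafh_share_alpha, config.fafh_share_beta, size=n_hh)
    fafh_exp = np.where(
        participates & (at_home_exp.to_numpy() > 0),
        share / (1.0 - share) * at_home_exp.to_numpy(),
        0.0,
    )
    fafh_rows = pd.DataFrame(
        {
            "household_id": households["household_id"].to_numpy()[fafh_exp > 0],
            "category_key": "FAFH",
            "quantity_g": np.nan,
            "expenditure": fafh_exp[fafh_exp > 0],
            "is_fafh": True,
        }
    )
    purchases = pd.concat([purchases, fafh_rows], ignore_index=True)

    # exact expectations: E[availability] per household and nutrient
    density = composition.densities[list(NUTRIENTS)].to_numpy()
    edible = composition.densities["edible_fraction"].to_numpy()
    contrib = (config.purchase_prob * expected_qty * edible[None, :]) @ density / 100.0
    expected = contrib / config.reference_days / ae[:, None]
    expected_df = pd.DataFrame(expected, columns=list(NUTRIENTS))
    expected_df.insert(0, "household_id", households["household_id"].to_numpy())

    pop_mean = {
        n: float(np.average(expected[:, j], weights=weights)) for j, n in enumerate(NUTRIENTS)
    }
    person_w = weights * households["n_members"].to_numpy()
    assignment = assign_income_quintiles(income / ae, person_w)
    labels = assignment.labels.to_numpy()
    ratio = {}
    for j, n in enumerate(NUTRIENTS):
        lo = np.average(expected[labels == "I", j], weights=weights[labels == "I"])
        hi = np.average(expected[labels == "V", j], weights=weights[labels == "V"])
        ratio[n] = float(hi / lo)

    truth = SurveyTruth(
        expected_availability=expected_df,
        population_mean=pop_mean,
        quintile_ratio=ratio,
        fafh_participation=config.fafh_participation,
        fafh_mean_share=config.fafh_participation
        * config.fafh_share_alpha
        / (config.fafh_share_alpha + config.fafh_share_beta),
    )
    return households, purchases, truth
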