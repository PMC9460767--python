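"""Design-aware population estimation for stratified two-stage surveys.

Household expenditure surveys sample primary sampling units (PSUs) within
explicit strata and attach an expansion factor (weight) to each household.
Population means of household-level quantities are ratio estimators
``Σ w_i y_i / Σ w_i``; their variance is approximated by first-stage
with-replacement Taylor linearization: linearized residuals are totalled per
PSU and their between-PSU dispersion accumulated within strata. Confidence
intervals use Student's t with ``df = #PSUs − #strata`` degrees of freedom.

Domain (subpopulation) estimates — e.g., per income quintile — keep the full
design and zero the out-of-domain contributions, so quintile estimates
recombine exactly to the overall mean when population-weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .nutrients import NUTRIENTS

logger = logging.getLogger(__name__)

QUINTILE_LABELS = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class SurveyDesign:
    """Per-household design metadata, aligned positionally with the data."""

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.weight)
        if not (len(self.stratum) == len(self.psu) == n):
            raise ValidationError("design arrays must have equal length")
        if n == 0:
            raise ValidationError("design must cover at least one household")
        if np.any(np.asarray(self.weight, dtype=float) <= 0):
            raise ValidationError("expansion factors must be positive")
        # a PSU id must not recur across strata
        pairs = pd.DataFrame({"stratum": self.stratum, "psu": self.psu})
        if (pairs.groupby("psu", sort=False)["stratum"].nunique() > 1).any():
            raise ValidationError("each PSU must belong to exactly one stratum")

    @classmethod
    def from_households(cls, households: pd.DataFrame) -> "SurveyDesign":
        return cls(
            stratum=households["stratum"].to_numpy(),
            psu=households["psu"].to_numpy(),
            weight=households["weight"].to_numpy(dtype=float),
        )

    @property
    def n_strata(self) -> int:
        return len(pd.unique(self.stratum))

    @property
    def n_psus(self) -> int:
        return len(pd.unique(self.psu))


@dataclass(frozen=True)
class SurveyEstimate:
    """Point estimate with design-based uncertainty."""

    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    n: int
    df: int

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n": self.n,
            "df": self.df,
        }


def weighted_mean(
    values,
    design: SurveyDesign,
    domain=None,
    level: float = 0.95,
    lonely_psu: str = "center",
) -> SurveyEstimate:
    """Design-based weighted mean with Taylor-linearized confidence interval.

    Parameters
    ----------
    values : array-like
        One value per household, aligned with the design.
    domain : boolean array-like, optional
        Subpopulation indicator. The estimate is restricted to the domain but
        every PSU still contributes (zeroed outside), the standard
        subpopulation convention.
    lonely_psu : {"center", "merge"}
        A stratum with a single PSU has no within-stratum dispersion. With
        ``"center"`` its PSU total is centered at the grand mean of PSU
        totals; with ``"merge"`` all lonely strata are pooled into one
        pseudo-stratum. Either emits a warning.
    """
    y = np.asarray(values, dtype=float)
    w = np.asarray(design.weight, dtype=float)
    if len(y) != len(w):
        raise ValidationError("values and design must have equal length")
    if domain is None:
        d = np.ones(len(y))
    else:
        d = np.asarray(domain, dtype=bool).astype(float)
    if np.isnan(y[d.astype(bool)]).any():
        raise ValidationError("missing values inside the estimation domain")

    wd = w * d
    W = wd.sum()
    if W <= 0:
        raise DegenerateDataError("empty estimation domain")
    est = float((wd * np.where(d > 0, y, 0.0)).sum() / W)

    # linearized residuals of the ratio-mean estimator
    z = wd * (np.where(d > 0, y, 0.0) - est) / W

    frame = pd.DataFrame({"stratum": design.stratum, "psu": design.psu, "z": z})
    psu_totals = frame.groupby(["stratum", "psu"], sort=False)["z"].sum().reset_index()

    if lonely_psu not in ("center", "merge"):
        raise ValidationError("lonely_psu must be 'center' or 'merge'")
    psu_counts = psu_totals.groupby("stratum", sort=False)["psu"].size()
    lonely = psu_counts.index[psu_counts == 1]
    if len(lonely):
        logger.warning("%d stratum(-a) contain a single PSU (%s handling)", len(lonely), lonely_psu)
        if lonely_psu == "merge":
            psu_totals.loc[psu_totals["stratum"].isin(lonely), "stratum"] = "__lonely_merged__"

    grand_mean = psu_totals["z"].mean()
    variance = 0.0
    for _, grp in psu_totals.groupby("stratum", sort=False):
        n_h = len(grp)
        if n_h > 1:
            zbar = grp["z"].mean()
            variance += n_h / (n_h - 1) * ((grp["z"] - zbar) ** 2).sum()
        else:
            variance += ((grp["z"].iloc[0] - grand_mean) ** 2)
    se = float(np.sqrt(variance))

    n_psus = len(frame.groupby(["stratum", "psu"], sort=False))
    dof = n_psus - design.n_strata
    n_dom = int(d.sum())
    if se == 0.0:
        lo = hi = est
    else:
        t_crit = float(stats.t.ppf((1 + level) / 2, max(dof, 1)))
        lo, hi = est - t_crit * se, est + t_crit * se
    return SurveyEstimate(estimate=est, se=se, ci_lower=lo, ci_upper=hi, n=n_dom, df=dof)


def weighted_quantile(values, weights, probs):
    """Interpolated weighted quantiles on the cumulative weight function.

    Plotting positions are ``p_i = S_i / (S_n + w̄)`` where ``S_i`` is the
    cumulative weight through the i-th sorted value and ``w̄`` the mean
    weight; under equal weights this reduces to the Weibull position
    ``i / (n + 1)``. Quantiles are linear interpolations between adjacent
    sorted values, clamped to the data range at the extremes.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("quantile weights must be positive")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    positions = cum / (cum[-1] + w.mean())
    p = np.atleast_1d(np.asarray(probs, dtype=float))
    out = np.interp(p, positions, v)
    return out if np.ndim(probs) else float(out[0])


@dataclass(frozen=True)
class QuintileAssignment:
    """Household → income-quintile labels plus the weighted cut points."""

    labels: pd.Series  # ordered categorical I..V, aligned to the input index
    cut_points: np.ndarray  # four nondecreasing weighted quantiles (p = .2, .4, .6, .8)


def assign_income_quintiles(income_per_ae, person_weights) -> QuintileAssignment:
    """Assign households to weighted income quintiles.

    Cut points are weighted quantiles at p = 0.2, 0.4, 0.6, 0.8 of the
    person-weighted distribution of income per equivalent adult (person
    weight = expansion factor × household size). A household whose income
    ties a cut point goes to the lower quintile.
    """
    income = pd.Series(np.asarray(income_per_ae, dtype=float))
    if isinstance(income_per_ae, pd.Series):
        income.index = income_per_ae.index
    cuts = weighted_quantile(income.to_numpy(), person_weights, [0.2, 0.4, 0.6, 0.8])
    cuts = np.asarray(cuts, dtype=float)
    if not np.all(np.diff(cuts) > 0):
        logger.warning("degenerate income distribution: quintile cut points are not distinct")
    idx = np.searchsorted(cuts, income.to_numpy(), side="left")
    labels = pd.Series(
        pd.Categorical.from_codes(idx, categories=list(QUINTILE_LABELS), ordered=True),
        index=income.index,
    )
    return QuintileAssignment(labels=labels, cut_points=cuts)


def quintile_nutrient_table(
    availability: pd.DataFrame,
    assignment: QuintileAssignment,
    design: SurveyDesign,
    nutrients=NUTRIENTS,
) -> pd.DataFrame:
    """Per-quintile design-based estimates for each nutrient (long format).

    Each cell is a subpopulation weighted mean over the quintile's households
    under the full design. Returns columns
    ``quintile, nutrient, estimate, se, ci_lower, ci_upper, n, df``.
    """
    rows = []
    labels = assignment.labels.to_numpy()
    for q in QUINTILE_LABELS:
        in_q = labels == q
        if not in_q.any():
            raise DegenerateDataError(f"income quintile {q} is empty")
        for nutrient in nutrients:
            est = weighted_mean(availability[nutrient].to_numpy(), design, domain=in_q)
            rows.append({"quintile": q, "nutrient": nutrient, **est.as_dict()})
    return pd.DataFrame(rows)


def percent_excess(higher: float, lower: float) -> float:
    """Percentage by which ``higher`` exceeds ``lower`` (e.g., quintile V over I)."""
    if lower <= 0:
        raise ValidationError("reference value must be positive")
    return (higher / lower - 1.0) * 100.0


@dataclass
class FafhSummary:
    """FAFH expenditure diagnostics plus the count of households excluded
    from the share estimate for having zero total food expenditure."""

    table: pd.DataFrame
    n_zero_expenditure_excluded: int


def fafh_summary(
    purchases: pd.DataFrame,
    households: pd.DataFrame,
    design: SurveyDesign,
    reference_days: int = 7,
    year_index: float = 1.0,
    base_index: float = 1.0,
) -> FafhSummary:
    """Food-away-from-home expenditure diagnostics under the survey design.

    Four estimates: percentage of households with positive FAFH expenditure;
    daily per-equivalent-adult constant-price expenditure on food at home;
    the same for all food; and the mean household-level FAFH share of total
    food expenditure (as a percentage). Households with zero total food
    expenditure are excluded from the share estimate and counted.
    """
    from .conversion import deflate  # local import avoids a cycle

    exp = purchases.copy()
    exp["expenditure"] = deflate(exp["expenditure"].fillna(0.0), year_index, base_index)
    by_hh = exp.groupby(["household_id", "is_fafh"])["expenditure"].sum().unstack(fill_value=0.0)
    at_home = by_hh.get(False, pd.Series(0.0, index=by_hh.index))
    fafh = by_hh.get(True, pd.Series(0.0, index=by_hh.index))

    hh = households.set_index("household_id")
    at_home = at_home.reindex(hh.index, fill_value=0.0)
    fafh = fafh.reindex(hh.index, fill_value=0.0)
    total = at_home + fafh
    denom = reference_days * hh["equivalent_adults"].to_numpy(dtype=float)

    has_fafh = (fafh > 0).to_numpy(dtype=float) * 100.0
    daily_home = at_home.to_numpy() / denom
    daily_total = total.to_numpy() / denom

    nonzero = total.to_numpy() > 0
    n_excluded = int((~nonzero).sum())
    share = np.zeros(len(total))
    share[nonzero] = fafh.to_numpy()[nonzero] / total.to_numpy()[nonzero] * 100.0

    rows = {
        "pct_households_fafh": weighted_mean(has_fafh, design),
        "daily_pae_expenditure_at_home": weighted_mean(daily_home, design),
        "daily_pae_expenditure_all_food": weighted_mean(daily_total, design),
        "fafh_share_of_food_expenditure_pct": weighted_mean(share, design, domain=nonzero),
    }
    table = pd.DataFrame(
        [{"measure": k, **v.as_dict()} for k, v in rows.items()]
    )
    return FafhSummary(table=table, n_zero_expenditure_excluded=n_excluded)


def trend_series(
    availability: pd.DataFrame, households: pd.DataFrame, nutrients=NUTRIENTS
) -> pd.DataFrame:
    """Year-by-year design-based means of nutrient availability (long format).

    ``availability`` and ``households`` both need a ``year`` column; each
    year's estimates use that year's own design.
    """
    rows = []
    for year, hh_year in households.groupby("year", sort=True):
        avail = availability.loc[availability["year"] == year]
        avail = avail.set_index("household_id").reindex(hh_year["household_id"]).reset_index()
        design = SurveyDesign.from_households(hh_year)
        for nutrient in nutrients:
            est = weighted_mean(avail[nutrient].to_numpy(), design)
            rows.append({"year": year, "nutrient": nutrient, **est.as_dict()})
    return pd.DataFrame(rows)
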