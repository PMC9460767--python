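# Methods

## The estimand

`heisnutr` estimates *availability*, not intake: the nutrients contained in
food acquired for consumption at home, expressed per equivalent adult per
day. Availability ignores cooking losses, intra-household allocation and
food eaten away from home, so it is an upper bound on at-home intake and a
lower bound on total intake. These are inherent properties of expenditure
data, not implementation choices; they are restated under *Limitations*.

## Conversion-table construction

Each expenditure category's nutrient profile is an aggregate over the foods
paired to it from composition sources. The pipeline per category is:

1. **Standardization.** Every food's nutrient amounts (reported for an
   arbitrary portion mass) are rescaled to 100 g of edible portion.
   Densities are invariant under portion rescaling by construction.
   Vitamin A is collapsed to retinol activity equivalents before scaling,
   with the standard divisors 12 (β-carotene) and 24 (other provitamin-A
   carotenoids); both divisors are configurable arguments of
   `compute_rae`.
2. **Outlier flags.** Per nutrient, Tukey's fences
   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are computed from the non-missing values.
   Quartiles use linear interpolation between order statistics at positions
   `1 + (n−1)p` — the common default in scientific software; the choice is
   documented here because different quartile estimators move fences
   noticeably at the n ≤ 12 typical of category pairings.
3. **Elimination.** Foods flagged in ≥ 2 nutrients (threshold configurable)
   are removed entirely and logged; flagged values of retained foods are
   excluded from that nutrient's aggregate only.
4. **Aggregation.** Mean by default; median available (`method="median"`).
   The edible fraction is aggregated with the same estimator as the
   nutrients, for symmetry.

Numerical conventions, chosen where the procedure is genuinely open:

- **Boundary.** The fence interval is closed: a value exactly on a fence is
  not an outlier. The comparison carries a relative guard of 1e-9 of the
  fence scale so that values equal to a fence up to floating-point
  round-off stay inside; without it, a category of identical foods
  (zero-width fence) flags ulp-level jitter introduced by the
  portion-rescaling arithmetic.
- **Single pass.** Fences are computed once from all items; item drops and
  per-value exclusions do not trigger recomputation. Iterating would remove
  progressively milder values and has no principled stopping rule at these
  sample sizes.
- **Missing vs zero.** A blank nutrient cell is missing information and is
  excluded from fences and aggregates; a zero is a measured zero and
  participates fully. A nutrient with no usable value in a category is
  emitted missing with a warning — the signal to repeat pairing from
  additional composition sources.
- **Degenerate inputs.** Single-item categories yield no flags (their
  fences collapse onto the lone value). A category losing every item
  raises; a nutritive category with no paired foods is reported, not
  fatal.

False positives are expected behavior: on continuously distributed clean
data, Tukey fences flag a small tail (a few percent per nutrient at
n ≤ 12), so a handful of uncontaminated foods are dropped from a large
table. This trims tails symmetrically and moves category means by well
under the noise level; it is the price of a simple, replicable rule.

## Conversion

Per household: sum of `quantity × edible fraction × density / 100` over
food-at-home purchases, divided by the reference period (7 days by default,
configurable) and by equivalent adults. Summation precedes division; the
two orders are algebraically identical, this one is fixed for
reproducibility of intermediate artifacts. Households with no food-at-home
purchases are retained with zero availability — dropping them would bias
population means upward; a flag to exclude them is deliberately absent.

The equivalence scale is a required configuration input (age bands with
per-member weights, reference adult 1.0). Official scales — e.g., the
CONEVAL scale used with Mexican data — are distributed by their agencies,
not hard-coded here. The built-in default (under 5 y: 0.70; 5–13 y: 0.80;
14+ y: 1.00) is **illustrative only** and marked as such in its docstring.

FAFH records carry expenditure but no quantity; no defensible imputation
of nutrients from expenditure alone exists, so they are excluded from
conversion and surfaced in expenditure diagnostics instead: share of
households with positive FAFH spending, daily per-equivalent-adult
constant-price expenditure at home and on all food, and the mean
household-level FAFH share of food expenditure (households with zero food
expenditure are excluded from the share and counted). Deflation to
constant prices is `expenditure × base index / year index`.

## Survey estimation

Means are ratio estimators under the stratified two-stage design. Variance
is first-stage with-replacement Taylor linearization: residuals
`zᵢ = wᵢ(yᵢ − ŷ)/W` are totalled per PSU; within stratum *h* with
`n_h` PSUs the contribution is `n_h/(n_h−1) · Σ(z_hc − z̄_h)²`. Intervals
use Student's t with `df = #PSUs − #strata`; with zero estimated variance
the interval collapses to the point. Subpopulation (quintile) estimates
zero out-of-domain contributions and keep every PSU, so population-weighted
quintile estimates recombine exactly to the overall mean.

- **Lonely PSUs.** A stratum with a single PSU contributes
  `(z_h1 − z̄)²` centered at the grand mean of PSU totals (warned);
  `lonely_psu="merge"` pools lonely strata instead. Both are standard
  survey-software conventions.
- **Weighted quantiles.** Quintile cut points interpolate the cumulative
  weight function at plotting positions `pᵢ = Sᵢ/(Sₙ + w̄)`, which reduce
  to the Weibull positions `i/(n+1)` under equal weights. Ties at a cut
  point go to the lower quintile; an all-equal income distribution puts
  everyone in quintile I with a warning.
- Quintiles are computed on income per equivalent adult, person-weighted
  (expansion factor × household size), matching per-capita reporting
  adjusted by equivalence scales.

## The synthetic generator

`heisnutr.simulate` emulates the *structure* of an ENIGH-like survey so the
pipeline is testable without microdata: 245 expenditure categories of which
9 are non-nutritive; multi-source composition records (a dominant source
per category, occasional second sources); a stratified two-stage frame with
expansion factors; log-normal income; 7-day recall; FAFH as
expenditure-only records. All draws flow from one seed, and every generated
data set ships with exact truth records (true densities, per-household
expected availability, population means, quintile ratios, FAFH parameters)
computed in closed form from the generating expectations.

Default conditions, fixed once:

- **Category densities.** Each category is dominated by one nutrient drawn
  from a high log-uniform range, the rest from low ranges — a stylized
  version of real categories (cereals are energy-dense, citrus is
  vitamin-C-dense). Item densities are the category truth times log-normal
  noise with σ = 0.01: generated categories emulate nutritionally
  homogeneous item lists, so aggregation error is dominated by
  contamination handling rather than sampling noise. 6–12 items per
  category; 2% of nutrient values missing.
- **Contamination.** Five percent of items, multiplied by 10× in two or
  three nutrients — the error pattern (unit slips, transcription) the
  fence-plus-drop rule targets. Placement is collision-free: at most one
  planted outlier per category×nutrient cell and two contaminated items per
  category. Overlapping outliers inflate the fence itself (the fences'
  breakdown point) and would make planted errors silently undetectable;
  a generator that plants unrecoverable errors cannot verify the drop-log
  bookkeeping, which is its purpose.
- **Income gradient.** Purchases scale with equivalent adults; the
  category mix shifts with income per equivalent adult through per-category
  elasticities equal to the gradient coefficient of the category's dominant
  nutrient (defaults: 0.03 energy, 0.11 protein, 0.19 vitamin A, 0.31
  vitamin C, 0.02 iron, 0.03 zinc — a stylized rich-world food gradient:
  strong in vitamins and protein, nearly flat in energy and minerals).
  True quintile ratios are computed from the generated population's exact
  expectations rather than from a formula, so they are consistent with the
  data by construction.
- **FAFH.** 60% participation; the participant share of food expenditure is
  Beta(2.5, 3.5) (mean ≈ 0.42), giving a population-level FAFH share of
  roughly a quarter of food spending.
- **Scale.** 10 strata × 4 PSUs × 10 households and weekly category
  quantities of 80–800 g, sized so the default world has ~2000 kcal per
  equivalent adult per day and simulation studies (500 replicate surveys
  for confidence-interval calibration) complete in seconds to minutes on
  one CPU.

What passing on synthetic data does **not** show: robustness to real
category heterogeneity (real categories mix dissimilar foods, where mean
and median profiles genuinely diverge), to reporting and recall error in
purchases, to unit-conversion problems in native survey units, or to
informative weights. The generator's noise is well-behaved by design;
results on real microdata depend on pairing quality and data cleaning
upstream of this package.

## Limitations

- Raw-food profiles: cooking and preparation losses (relevant for vitamin C
  and zinc) are not modelled.
- FAFH nutrients are not imputed; estimates understate total availability,
  more so where eating out is common.
- Availability ≠ intake: no intra-household allocation, no waste.
- Replicate-weight variance (BRR/jackknife), small-area estimation and
  formal trend tests are out of scope.
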