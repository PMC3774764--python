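# Methods

## The estimand and the estimator

The core analysis regresses district-level stunting prevalence (percent of
children with height-for-age z-score, HAZ, below −2; severe stunting below
−3) on the natural log of the percent of households practicing open
defecation (OD), with districts weighted by population and standard errors
robust to heteroscedasticity. The model is built in five cumulative stages
so the sensitivity of the OD coefficient to confounder adjustment is
visible:

1. `stunting ~ ln(OD)`
2. `+ urban + urban²` (urban households rarely defecate in the open and
   urban children differ in many other ways)
3. `+ ln(MPCE) + calories + cereal calories + household size` (wealth and
   nutrition confounders; expenditure enters in logs by convention)
4. `+ literacy + female literacy` (maternal education / social status)
5. `+ IMR` — *not* a further control but a mechanism probe: infant
   mortality proxies the early-life disease environment, so if the OD
   association operates through fecal exposure, adding IMR should absorb
   part of the OD coefficient.

The quadratic urban term uses the raw percentage (not centered), matching
the printed-coefficient scale of published tables of this kind.

### Weighted least squares and the sandwich covariance

Weights are analytic weights: internally rescaled to sum to n so that
results are invariant to the scale of the weight column (total vs. under-5
population, say). Coefficients minimize `Σ wᵢ(yᵢ − xᵢ'β)²`; the weighted R²
is `1 − RSSw/TSSw` with the total sum of squares centered at the weighted
mean. The robust covariance is the sandwich on the √w-whitened regression,

    V = (X'WX)⁻¹ (Σᵢ wᵢ² eᵢ² xᵢxᵢ') (X'WX)⁻¹ · n/(n−k),

i.e. HC1; HC0/HC2/HC3 are available (HC2/HC3 divide squared residuals by
powers of one minus the whitened leverage), as is the classical
homoscedastic `s²(X'WX)⁻¹`. Two-sided p-values use the t distribution with
n − k degrees of freedom, k counting the intercept. Rows with a missing
value in any used column are dropped per model (listwise deletion) with the
count logged — this is why the IMR stage typically has a smaller n.

### Box-Cox selection of the exposure transform

There is no a priori reason for stunting to be linear in the OD percentage,
so the transform is chosen from the Box-Cox family applied to the
*independent* variable: `(x^λ − 1)/λ`, which tends to `ln x` as λ → 0.
Because the outcome is untransformed, the likelihood carries no Jacobian
term; for each λ the Gaussian likelihood is concentrated over the
regression coefficients and error variance, giving

    ℓ(λ) = −(n/2)(1 + ln(2π·RSS(λ)/n)).

λ̂ maximizes ℓ over a coarse grid (default step 0.05 on [−3, 3], bounds wide
enough to bracket any plausible candidate) refined by bounded Brent search
(tolerance 1e-6). The 95% CI inverts the likelihood-ratio test: the λ where
ℓ drops χ²₁(0.95)/2 ≈ 1.921 below the maximum, found by root bracketing and
clamped to the search bounds when the profile never drops that far (flat
profiles are common in small, noisy samples). LR p-values against λ₀ ∈
{−1, 0, 1} are reported by default. The profile regression is unweighted by
default (a weighted option exists), is bivariate by default (covariates
configurable), and λ̂ is *not* invariant to rescaling x — the fit records
that the exposure is on the percent scale.

### Marginal effect and gap decomposition

A "10% increase in OD" is read proportionally (OD × 1.10), so the implied
prevalence change is `β·ln(1.1)`; the additive-in-logs approximation `β/10`
is exposed as an option and rounds to the same headline for coefficients
near 7. The share of the stunting gap between a low-performing and a
high-performing group of districts attributable to their OD difference is

    share = β · (ln OD_low − ln OD_high) / (stunting_low − stunting_high).

Applied to the published group means (OD 76.3 vs 33.8%, stunting 59.1 vs
35.9%) this gives 38.7% with the bivariate coefficient (11.02) and 24.9%
with the adjusted coefficient (7.082). The originating study quotes a 35–55%
range for the same decomposition; that range does not follow from this
formula with the printed inputs, and the study's exact arithmetic is not
stated. The formula above is implemented as defined here; the discrepancy is
documented rather than resolved.

## The dichotomization power study

Thresholding HAZ at −2/−3 discards within-category variation. To quantify
the cost, the Monte Carlo procedure repeats, per replicate:

1. draw a simple random sample of children **without replacement**
   (default 20,000);
2. collapse to PSU means: OD fraction, mean HAZ, fraction stunted
   (HAZ < −2, strict), fraction severely stunted (HAZ < −3, strict);
3. regress each of the three summaries on the PSU OD fraction by unweighted
   OLS with classical inference (weighting by PSU sample size is an
   option);
4. record slope, t and R².

All PSUs with at least one sampled child enter (a `min_psu_n` filter
exists, default 1). The summary statistic is the *win fraction*: the share
of replicates in which the mean-HAZ regression's R² strictly exceeds both
dichotomized regressions' R², and likewise for |t| — absolute value because
the continuous slope is negative while the dichotomized slopes are
positive. Defaults are 1,000 replicates of 20,000 children; the acceptance
script uses 200 replicates, which is ample for a win fraction bounded away
from the 0.9 reference line.

## The synthetic-data generator

The generator defines the study conditions the tests run under.

**Districts** (default n = 112): the OD percentage is `100·Beta(2.5, 0.8)`
clipped to [0.1, 99.9] — left-skewed (skewness ≈ −0.9 in large samples),
mean ≈ 76%, with occasional low-coverage districts, emulating the strongly
negatively skewed district OD distributions seen in census data. Stunting
follows the structural model
`30 + 7·ln(OD%) + Σ controls + N(0, 4²)` clipped to [0, 100]; the default
control effects (−0.15 per literacy point, +1.0 per household member) keep
the mean near 56%. Severe stunting uses the same slope with a 24-pp lower
intercept, floored at 0 and capped at the stunting value (no joint model is
claimed by the source literature; this is the package's choice). IMR is
`6.6 + 15·ln(OD%) + N(0, 10²)`, giving an IMR–ln(OD) correlation near 0.47;
adding `imr` to `control_effects` routes part of the OD effect through IMR,
making it a partial mediator for the attenuation experiments. Two districts
have IMR marked missing by default, exercising the listwise-deletion path.
Other controls are drawn independently with marginals matching published
descriptive tables of such district panels (literacy ~ N(66, 8), MPCE
log-normal around ₹540/month, calories ~ N(2056, 180) with a cereal share
near 0.69, household size ~ N(6.3, 0.9)); joint correlations among controls
are not modeled — they are unreported in aggregate sources, so independence
is the explicit free choice here.

**Children** (default 2,000 PSUs × 20 children ≈ 40,000): each PSU draws an
OD rate from Beta(mean 0.55, concentration 2), each child's household OD
indicator is Bernoulli in that rate, and HAZ ~ N(−0.8 − 2.0·rate, 1.2²).
The default scale keeps a 1,000-replicate power study in the low minutes
and a 200-replicate one in seconds.

What the generator does **not** emulate: survey design (strata, sampling
weights, non-response), spatial correlation between districts, measurement
error in height, age structure, or control–control correlations. Passing
tests therefore demonstrate that the estimators and the pipeline are
correct under the assumed data-generating process — not that the published
coefficients are recoverable, which would require the real merged district
data and is out of scope.

## Numerical and design notes

- Robust variant: sources of this kind say only "heteroscedasticity-robust";
  HC1 is the common software default and is adopted here, with the variant
  exposed.
- Percentages are clipped into [0, 100] after noise, with clip counts
  logged, so record invariants hold for every generated dataset.
- Significance stars use strict inequalities († p < 0.10, * p < 0.05,
  ** p < 0.01); p = 0.10 exactly earns no dagger.
- Display rounding is 4 significant figures for coefficients and SEs,
  3 decimals for R².
- A constant column's skewness is reported as NaN (undefined), never 0.
- Degenerate perfect fits (RSS = 0) make the concentrated likelihood
  infinite; the profile reports +inf and the estimator surfaces the grid
  point rather than silently failing.
- Problem sizes in the acceptance script — 100 recovery replicates at
  n = 112, 200 power replicates of 20,000 children — were chosen to give
  stable Monte Carlo fractions (binomial SE below 3 points) while keeping a
  full run in seconds.

## Known limitations

- The ecological design itself: group-level associations cannot identify
  individual-level or causal effects, and the package makes no attempt to.
- The Box-Cox CI is a profile-likelihood interval; its coverage is
  asymptotic and can exceed the nominal level when the signal is weak
  (the profile is then nearly flat and the CI very wide).
- The gap-share decomposition inherits the coefficient's scale only; it is
  silent about uncertainty (no CI is propagated).
- PSU-level regressions treat collapsed means as observations; PSUs with
  tiny sampled counts contribute noisier means, which the default
  unweighted fit ignores.
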