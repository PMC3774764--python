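# ecostunt

Ecological regression tools for studying the district-level association
between open defecation (OD) and child stunting, together with a Monte Carlo
study of the statistical power lost when continuous child height data are
dichotomized into stunting indicators.

The package is aimed at epidemiologists and applied statisticians working
with aggregate (district- or cluster-level) survey data on child growth and
sanitation. It provides:

- **`synthetic_data`** — seeded generators for district tables (stunting %,
  severe stunting %, OD %, IMR, urbanization, literacy, expenditure,
  calories, household size, population weights) and PSU-clustered child
  records (household OD indicator, height-for-age z-score). The district
  generator has a known log-linear structural effect, so every estimator
  downstream can be validated by parameter recovery.
- **`regression_core`** — weighted least squares with analytic-weight
  semantics and heteroscedasticity-robust (HC0–HC3, default HC1) sandwich
  covariance:
  `V = (X'WX)⁻¹ (Σᵢ wᵢ²eᵢ²xᵢxᵢ') (X'WX)⁻¹ · n/(n−k)`.
- **`transform_selection`** — Box-Cox selection of the exposure transform
  `(x^λ − 1)/λ` (→ ln x as λ → 0) by maximizing the concentrated Gaussian
  profile likelihood `ℓ(λ) = −(n/2)(1 + ln(2π·RSS(λ)/n))`, with a
  likelihood-ratio 95% CI (profile drop of χ²₁(0.95)/2 ≈ 1.92).
- **`ecological_analysis`** — the five-stage adjustment sequence
  (1: ln OD; 2: + urban, urban²; 3: + ln MPCE, calories, cereal calories,
  household size; 4: + literacy, female literacy; 5: + IMR as a mechanism
  probe), population-weighted with robust SEs; descriptive statistics with
  moment-ratio skewness; marginal effects `β·ln(1 + Δ%/100)`; and the
  between-group gap decomposition
  `β·(ln OD_low − ln OD_high)/(stunting_low − stunting_high)`.
- **`dichotomization_power`** — subsample children, collapse to PSU means,
  regress mean HAZ and the stunted fractions (HAZ < −2, HAZ < −3) on the
  PSU OD fraction, and compare R² and |t| across specifications.

## Worked example

```python
import ecostunt as e

# synthetic 112-district survey with a true ln(OD) effect of 7 pp/log-unit
df = e.districts_to_frame(e.gen_districts(e.DistrictGenParams(seed=1)))

table = e.run_staged_models(df, "stunting_pct")
res = table.result(4)                       # fully adjusted stage
print(res.coef("ln(od_pct)"), res.se("ln(od_pct)"), res.r_squared)
# 5.984  1.555  0.173
print(e.marginal_effect(res.coef("ln(od_pct)"), 10))
# 0.57   <- pp more stunting per 10% (x1.10) more open defecation
```

The stage-4 estimate 5.98 (robust SE 1.56) sits well within two standard
errors of the generating effect of 7, and the implied marginal effect says a
10% proportional rise in open defecation goes with about 0.6 percentage
points more stunting in this replicate. With the published study's adjusted
coefficient, `e.marginal_effect(7.082, 10)` gives 0.675 ≈ 0.7 pp.

The same pipeline is scriptable from a shell:

```
ecostunt simulate districts --seed 1 --out districts.csv
ecostunt fit --data districts.csv --outcome stunting_pct
ecostunt boxcox --data districts.csv
ecostunt simulate children --seed 1 --out children.csv
ecostunt power-study --children children.csv --sample-size 20000 --reps 1000 --seed 1
```

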