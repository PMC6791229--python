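# greyhybrid

Grey-model / machine-learning hybrid forecasting for short annual count
series, built around the incidence of occupational diseases in China
(2005–2017), a packaged 13-point series with the number of reporting
provinces per year.

Occupational-disease surveillance (and many comparable public-health
settings) yields little more than one count per year. Classical time-series
and machine-learning models need far more data than that. Grey systems
theory addresses exactly this regime: the GM(1,1) family turns a short,
strictly positive sequence x⁽⁰⁾ = (x⁽⁰⁾(1), …, x⁽⁰⁾(n)) into its
accumulated series x⁽¹⁾(k) = Σᵢ₌₁..k x⁽⁰⁾(i), fits a two-parameter linear
form by ordinary least squares, and restores predictions by first
differencing. This package implements five family members and a two-stage
hybrid on top of them.

## Models

With background value z⁽¹⁾(k) = (x⁽¹⁾(k) + x⁽¹⁾(k−1))/2:

| model | estimated form (k = 2…n) | prediction of x⁽¹⁾ |
|---|---|---|
| EGM | x⁽⁰⁾(k) = −a z⁽¹⁾(k) + b | (x⁽⁰⁾(1) − b/a) e^(−a(k−1)) + b/a |
| EDGM | x⁽⁰⁾(k) = −a z⁽¹⁾(k) + b | x̂⁽¹⁾(k) = ((1−a/2) x̂⁽¹⁾(k−1) + b)/(1+a/2) |
| ODGM | x⁽⁰⁾(k) = −a x⁽¹⁾(k) + b | x̂⁽¹⁾(k) = (x̂⁽¹⁾(k−1) + b)/(1+a) |
| DGM | x⁽¹⁾(k) = β₁ x⁽¹⁾(k−1) + β₂ | same recursion |
| Verhulst | x⁽⁰⁾(k) = −a z⁽¹⁾(k) + b z⁽¹⁾(k)² | logistic time response, capacity a/b |

The Verhulst variant treats the raw series itself as the S-curve state
x⁽¹⁾ and reports its logistic time response directly. ODGM, EDGM and DGM
reproduce homogeneous exponential sequences q·r^(k−1) exactly; all five
preserve the first observation exactly.

The **hybrid** stage uses the five models' restored fitted values
(training years) and forecasts (held-out years) as a five-column feature
matrix with the actual counts as labels, then fits a second-stage
regressor: k-nearest neighbours (k = 2, uniform or inverse-distance),
support-vector regression (linear/polynomial/radial/sigmoid kernels),
random forest (mtry = 1, ntree = 30), gradient boosting (100 rounds,
η = 0.1, γ = 0.5, depth 3, subsample 0.5), or a single-hidden-layer
sigmoid network (5 units, weight decay 1e−8, ≥50 random restarts selected
by training RMSE). Candidates are compared by MAPE and RMSE on the
chronologically held-out years, with errors signed as actual − forecast.

## Worked example

```
$ greyhybrid fit-gm --fixture china --out gm_out
wrote gm_out/fitted_values.csv and gm_out/gm_accuracy.csv
```

The first rows of `fitted_values.csv`:

```
year,actual,EGM,EDGM,ODGM,DGM,VERHULST
2005,12212,12212,12212,12212,12212,12212
2006,11805,14255,14268,14136,14415,14677
2007,14296,15805,15821,15700,15954,17261
```

Every model anchors 2005 at the observed 12212; the 2006 row shows the
five restored fitted values. `gm_accuracy.csv` reports, e.g., EGM training
MAPE 13.02 % and testing MAPE 47.51 % — the grey models capture the trend
but over-shoot the 2015–2017 window badly, which is precisely why the
hybrid stage exists.

```
$ greyhybrid fit-hybrid --fixture china --seed 20190929 --out hybrid_out
selected knn[k=2,uniform]: testing MAPE 6.89, RMSE 2064.46
```

On this series the bounded second-stage regressors cut the held-out MAPE
from ~47 % (grey models alone) to 6.9–9.7 %. The sigmoid network fits the
training window almost perfectly (MAPE 0.06 %) but its bounded output
saturates at the largest training label for the growing 2015–2017
features, giving a held-out MAPE of 9.5–9.7 % — see `docs/methods.md` for
why restart selection by training RMSE always lands there.

Notes on conventions, confirmed against the packaged series:

- Grey models are fitted on **raw counts** by default. Per-province
  normalization (`--normalize`) is available — dividing each count by that
  year's number of reporting provinces (29 in 2006, 31 in 2015–2017, 30
  otherwise) — but the reference fitted values above are only reproduced
  on the raw scale (the 2006 EGM value 14255 arises from raw counts), so
  normalization is never applied silently.
- The KNN cross-validation grid and the SVR constants beyond the kernel
  (cost 1, ε 0.1, degree 3, coef0 0, kernel coefficient 1/p, standardized
  features and labels) are documented defaults in the usual conventions of
  those estimators, not values fixed by the reference tables.

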