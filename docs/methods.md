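# Methods

## Scope and data model

The package forecasts short annual count series. The container
(`AnnualSeries`) enforces the two assumptions every downstream formula
relies on: years strictly consecutive (grey models assume equal spacing)
and values strictly positive (the least-squares forms divide by nothing,
but restoration and all percentage errors divide by the observations).
The packaged China occupational-disease series (13 annual counts,
2005–2017, with the number of reporting provinces per year) is the
reference dataset; everything else is generated synthetically.

Chronological splitting puts the first `round_half_up(n · f)` years in
training (clamped to leave ≥3 training and ≥1 test year), with default
f = 0.75 so the reference series splits 2005–2014 / 2015–2017. The split
is never shuffled: the evaluation question is genuine extrapolation.

Per-region normalization (counts divided by that year's number of
reporting regions) is provided but off by default: the reference fitted
values this package validates against arise from raw counts, so
normalization is an explicit, invertible preprocessing choice, applied to
the grey stage and undone (per-year multiplication) before any accuracy
is reported.

## Grey models

All five models estimate their two parameters by ordinary least squares
on the model's defining difference form, using an SVD-backed solver
rather than explicit normal equations — the accumulated series spans
several orders of magnitude and the normal-equations cross-products
square that spread. Genuine rank deficiency (e.g. the Verhulst design on
a constant series, whose two regressors z and z² are collinear) raises an
error instead of returning a least-norm artifact.

Conventions that matter:

- Indexing: k = 1…n maps to the training years; forecasts occupy
  k = n+1…n+h.
- First-value anchoring: restoration always re-inserts x⁽⁰⁾(1), so every
  model fits the first year exactly. Training accuracy deliberately
  includes this zero-error point in its denominator.
- Degenerate development coefficient: a constant series makes the
  even-form regression unidentifiable; EGM/EDGM then use the analytic
  a = 0 limit (x̂⁽¹⁾(k) = x⁽⁰⁾(1) + b(k−1)), which reproduces the constant
  exactly. Divisions by 1+a, 1±a/2 and the Verhulst denominator are
  guarded with a 1e−12 tolerance.
- Restored growth ratios: from k = 2 on, the restored EGM values grow by
  e^(−a) per step, EDGM by (1−a/2)/(1+a/2), ODGM by 1/(1+a), DGM by β₁.
  These identities (and exactness of ODGM/EDGM/DGM on homogeneous
  exponentials, to 1e−8 relative) are enforced as property tests.
- Verhulst out-of-sample convention: the fitted values are the logistic
  time response at k = 1…n, but forecast step h evaluates k = n+h+1 —
  one index step beyond the natural continuation. This convention was
  recovered from, and is required to reproduce, the tabulated reference
  predictions for the China series (both the predicted counts for
  2015–2017 and the accuracy statistics computed from them), and is kept
  so that hybrid features match those reference values. On a saturating
  series the practical effect is small (the response is near its
  carrying capacity a/b); users extending the package to other data
  should be aware the Verhulst predictor skips one step out of sample.
- Reporting: all computation and all accuracy metrics use unrounded
  values; integers (fitted-value tables) and 2-decimal rounding
  (accuracy tables) are applied half-up at the reporting layer only.

## Accuracy metrics

For actual Aₜ and forecast Fₜ, errors are signed eₜ = Aₜ − Fₜ; the five
statistics are ME = mean(e), RMSE = √mean(e²), MAE = mean|e|,
MPE = 100·mean(e/A), MAPE = 100·mean(|e|/A). An over-predicting model
therefore has negative ME and MPE. The Jensen orderings |ME| ≤ MAE ≤ RMSE
and |MPE| ≤ MAPE, scale equivariance, and agreement with an independent
loop-based recomputation are covered by tests.

## Hybrid stage

The feature matrix has one row per year and one column per grey model in
the fixed order EGM, EDGM, ODGM, DGM, VERHULST: restored fitted values
over the training window, forecasts over the test window. Labels are the
actual counts; test labels are used only for evaluation. Because of
first-value anchoring, the first training row is five copies of its own
label.

Second-stage estimators (all sklearn-compatible; training-window
predictions are in-sample, i.e. the query year is part of the fitted
model):

- **knn** — k = 2; uniform or inverse-distance weights. With
  inverse-distance weights each training point is its own zero-distance
  neighbour, so the in-sample fit is exact by construction.
- **svr** — the four standard kernels with cost 1, ε 0.1, degree 3,
  coef0 0, kernel coefficient 1/p, with features and labels standardized
  (the customary preprocessing of small-sample SVR); these constants are
  conventional defaults, not reference-fixed values.
- **rf** — random forest, mtry = 1, ntree = 30.
- **gbm** — gradient boosting (xgboost), 100 rounds, η = 0.1, γ = 0.5,
  depth 3, subsample 0.5, colsample 1, min_child_weight 1.
- **ann** — an in-package single-hidden-layer network: 5 logistic hidden
  units and a *logistic output unit*, sum-of-squares loss plus L2 weight
  decay (1e−8), trained by L-BFGS-B (≤10000 iterations, tolerance 1e−8)
  on inputs and labels min-max scaled to [0,1], from ≥50 random
  initializations U(−0.7, 0.7); the restart with the lowest
  training-window RMSE is kept. The bounded output unit is structural:
  predictions can never leave the training-label range, so the network
  saturates rather than extrapolates. One test cross-checks this
  implementation against the classical R reference implementation of the
  same architecture via Rscript.

Model selection minimizes testing MAPE, breaking ties by testing RMSE.
The subset search evaluates a regressor on all 2⁵−1 = 31 non-empty
grey-feature subsets with the same ranking (further ties: larger subsets
first, then lexicographic).

Seed policy: every stochastic family takes an explicit seed (restart
initializations derive from a `SeedSequence`); the CLI default is the
fixed documented constant 20190929.

## Behaviour on the reference series — what to expect

On the China series the grey models over-shoot the held-out years by
~47 % MAPE (21.5 % for the saturating Verhulst), and all hybrid families
improve on that substantially (6.9–9.7 %). Two structural effects
dominate the held-out window:

- Tree ensembles (rf/gbm) predict convex combinations of training
  labels, so their 2015–2017 predictions cannot exceed the training
  maximum even though the grey features keep growing — they undershoot a
  strongly growing series by construction (asserted as a range property).
- The sigmoid network's in-sample fit is near-perfect (training MAPE
  ≈ 0.06 %), and selection by training RMSE systematically prefers such
  interpolators. Their bounded outputs are already saturated over the
  2015–2017 feature range, so the selected network predicts the plateau
  at the largest training label (29 972) for all three held-out years,
  giving MAPE ≈ 9.7 % and RMSE ≈ 3 180 essentially independently of seed
  and restart count. Restarts that happen to generalize better exist,
  but no training-window criterion identifies them; this is a known
  limitation of best-training-fit restart selection on 10 training rows,
  and the reason the package reports the full per-family comparison
  rather than a single winner.

## Synthetic generator

`generate_series` produces the three regimes the model family
distinguishes: `geometric` (exact homogeneous exponential — the class
ODGM/EDGM/DGM reproduce to machine precision, used for exactness and
parameter-recovery tests), `logistic` (S-curve approaching a capacity —
the Verhulst regime), and `oscillating` (positive trend plus bounded
sine — data none of the models can fit exactly). Noise is multiplicative
log-normal so positivity is preserved; `noise_sd = 0` returns the exact
deterministic sequence, and fixed seeds give identical series. The
generator emulates the magnitude and length of annual surveillance
series; it does not emulate reporting artifacts (province-coverage
changes, case-definition revisions), so passing tests demonstrate
correctness of the algorithms, not robustness to real surveillance
quirks.

Default problem sizes in tests (n = 8–20 synthetic points, 100 seeds for
the parameter-recovery study) were chosen as the smallest sizes at which
the asserted properties are sharp; the reference-series computations use
the full 13-year fixture.
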