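# yieldcast

Ensemble machine-learning forecasting for county × year crop-yield panels.

Crop yields in a region like the US Corn Belt form a spatio-temporal panel:
one observation per (county, year), driven by weekly weather, static soil
properties, management (planting progress, plant population) and a steady
technology trend. Forecasting the next years from such a panel breaks the
IID assumption behind random k-fold cross-validation — rows from one year
share a weather draw, rows from one county share soil — so every model
evaluation here slides forward in time. `yieldcast` is aimed at
agronomists, forecasters and methods researchers who want to combine
several regression learners into a single forecast that is demonstrably no
worse than its best member on held-out history, and to interrogate what the
combined model has learned.

## The method

**Blocked sequential out-of-bag (OOB) predictions.** A window of 8
consecutive years trains every base learner; the following year is
predicted; the window advances one year. Stacking the validation-year
predictions gives an OOB matrix Ŷ (one column per learner j, one row per
held-out observation i) aligned with the true responses y. The first 8
years never appear as OOB rows, and no model ever sees a year at or after
the one it predicts.

**Optimized weighted ensemble.** Weights solve the convex quadratic
program

```
min_w  (1/n) Σᵢ (yᵢ − Σⱼ wⱼ ŷᵢⱼ)²     s.t.  Σⱼ wⱼ = 1,  wⱼ ≥ 0
```

Every unit vector eⱼ is feasible, so the optimum's OOB mean squared error
never exceeds that of any single base learner — nor of the equal-weight
average (wⱼ = 1/k) or the exponentially weighted average
(wⱼ ∝ exp(−eⱼ), eⱼ the learner's OOB RRMSE), which are the built-in
benchmarks. Stacked generalization (a second-level learner trained on the
OOB columns) is provided for comparison.

**Base learners** — OLS, LASSO (penalized RSS + λ‖β‖₁, intercept
unpenalized), random forest, XGBoost and LightGBM — all behind one
fit/predict contract.

**Around the core:** per-location linear trend features and per-state
compound-growth mean-yield features; min–max scaling fit on training rows;
three-stage feature selection (week-tag expert filter → permutation-
importance top-k → greedy |r| > 0.9 Pearson de-duplication); metrics RMSE,
RRMSE, MBE and mean directional accuracy; harvested-area-weighted
aggregation from county to agricultural-district and state scale;
partial-season scenarios that truncate weather at a cutoff week; and
partial-dependence plots of the weighted ensemble, whose PD curve is
provably the same convex combination of the members' PD curves. Feature
importance is the sample standard deviation of the PD values over the grid.

A seeded synthetic-panel generator (`yieldcast.synthetic`) emulates the
panel structure — per-location trends of 32–189 kg/ha/yr, weekly weather
blocks, redundant feature pairs, configurable feature effects — so the
entire stack is testable without external data.

## Worked example

```python
from yieldcast import (SyntheticConfig, generate_panel, split_by_year,
                       TrendFeaturizer, PanelMinMaxScaler, LearnerSpec,
                       WeightedEnsembleRegressor, rmse, rrmse, mbe)

panel = generate_panel(SyntheticConfig(
    n_locations=30, n_weather_vars=1, weather_weeks=(14, 44),
    noise_sd=600.0, effect_spec={"tmin_w21": -120.0, "tmin_w19": 90.0},
    seed=42))
train, test = split_by_year(panel, first_test_year=2016)

trender = TrendFeaturizer().fit(train)
train, test = trender.transform(train), trender.transform(test)
scaler = PanelMinMaxScaler().fit(train)
train, test = scaler.transform(train), scaler.transform(test)

specs = [
    LearnerSpec("linear", "linear"),
    LearnerSpec("lasso", "lasso", {"lam": 200.0}),
    LearnerSpec("random_forest", "random_forest", {"n_estimators": 100}, seed=0),
]
model = WeightedEnsembleRegressor(specs, method="optimized").fit(train)
for name, w in model.weights_.to_dict()["weights"].items():
    print(f"w[{name}] = {w:.3f}")
print(f"OOB MSE (optimized) = {model.weights_.oob_objective:,.0f}")
print(f"best single-learner OOB MSE = {min(model.oob_.learner_mse().values()):,.0f}")

pred = model.predict(test)
y = test.y.to_numpy()
print(f"test RMSE  = {rmse(y, pred):,.0f} kg/ha")
print(f"test RRMSE = {100 * rrmse(y, pred):.2f} %")
print(f"test MBE   = {mbe(y, pred):+.0f} kg/ha")
```

Output:

```
w[linear] = 0.000
w[lasso] = 0.557
w[random_forest] = 0.443
OOB MSE (optimized) = 353,030
best single-learner OOB MSE = 384,255
test RMSE  = 597 kg/ha
test RRMSE = 6.51 %
test MBE   = +81 kg/ha
```

The QP puts just over half the weight on the LASSO and the rest on the
random forest; their blend's OOB error (353k) undercuts the best single
learner (384k), and on the three held-out years the ensemble forecasts
county yields to within 6.5 % of the mean observed yield with a small
(+81 kg/ha) overestimation bias.

The same workflow is available from the shell — `yieldcast synth`,
`prepare`, `oob`, `ensemble`, `forecast`, `explain`; each subcommand's
`--help` describes its inputs.

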