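# Methods

This note documents the models and procedures implemented in `yieldcast`,
their assumptions, the numerical choices made where the design was open,
and what the synthetic-data tests do and do not establish about real
yield panels.

## Panel model and assumptions

The unit of observation is a (location, year) pair with a continuous
response in kg/ha, a nonnegative harvested-area weight, administrative
labels (state, agricultural district nested in state), and features tagged
by group: `weather` (weekly, week-of-year tag required), `management`
(weekly planting progress or static plant population), `soil` and `trend`
(static). The framework assumes:

* responses are comparable across locations after accounting for a
  location-specific linear technology trend;
* the predictive relationship between features and yield is stable enough
  over an 8-year window for a model trained on that window to be a
  reasonable forecaster of the following year;
* rows are *not* IID — years are the exchangeable blocks, which is why all
  validation is walk-forward and the out-of-bag (OOB) machinery is blocked
  by year.

## Trend features

Two constructed covariates carry the technology trend so that base
learners need not extrapolate it from weather and soil alone:

* `yield_trend`: per-location OLS of response on calendar year,
  Ŷᵢ = b₀ᵢ + b₁ᵢ·YEAR, fitted on training years only and evaluated on all
  rows (test years extrapolate the line). Each location therefore needs at
  least two training years; fitting fails loudly otherwise.
* `yield_avg`: for a training row, the training mean yield of its state in
  that year. For a test year t, the last training year's state mean is
  compounded by the mean relative year-on-year increment g of the state's
  training means: baseline·(1 + g)^(t − last_training_year). At horizon
  zero this reproduces the baseline exactly, so the two regimes join
  continuously. The baseline is the raw last-training-year state mean, not
  a fitted value; increments are taken between consecutive years of the
  training series.

Whether a row is "training" or "test" is inferred from its year relative
to the fitted last training year, so a single `transform` serves both.

## Scaling and three-stage feature selection

Min–max scaling maps each feature to [0, 1] using training min/max;
constant features map to 0; test values may leave the unit interval (no
clipping). The pipeline order is: construct trend features → fit scaling →
run selection. Selection must see the constructed features, and scaling
first keeps permutation importances comparable across feature units.

1. **Expert filter** — drops weather columns whose week lies outside the
   growing season (default weeks 14–44) and weekly planting-progress
   columns before the planting window (default week 14). The week
   boundaries are configuration, not constants, since sensible values vary
   by region.
2. **Permutation importance** — a random-forest-style learner is fitted on
   the training rows; a feature's importance is the mean increase in
   training MSE over `n_repeats = 5` seeded permutations of its column
   (scikit-learn's `permutation_importance` with a negated-MSE scorer).
   The top `n_keep = 80` features are retained, ties broken by column
   order.
3. **Correlation filter** — features are scanned in column order; one is
   dropped when its absolute Pearson correlation with an already-retained
   feature exceeds 0.9 (the earlier column wins). The retained set is
   re-checked against the full correlation matrix in the tests.

Trend-constructed features are force-retained by stages 2 and 3 and never
consume selection slots: the two trend columns are mutually correlated by
construction and a blind greedy scan would evict one of them. Constant
features are never silently dropped — they are retained and flagged in the
`SelectionReport`, because a constant column usually indicates an upstream
data bug worth surfacing.

## Walk-forward validation and blocked OOB

`make_walk_forward_plan` requires contiguous training years and produces
folds (years f…f+7 → year f+8), advancing one year until the final
training year is the validation year. Locations may be missing in some
years; a fold simply uses the rows that exist. The same plan drives both
hyperparameter tuning and OOB generation.

Tuning scores each candidate by validation MSE averaged over folds. The
built-in search is seeded uniform random sampling over a finite grid;
a Bayesian/TPE backend can be plugged in as a sampler callable, keeping
the package free of heavyweight optional dependencies.

`generate_oob` refits every learner per fold and records validation-year
predictions, giving an OOB matrix whose row count equals the training rows
minus the first 8 years of rows. Tests verify structurally that no
predicting model was fitted on any year at or after the year it predicts.

## Ensembles

Given the OOB matrix (y, Ŷ):

* **Optimized weights** minimize (1/n)‖y − Ŷw‖² over the probability
  simplex. The QP is solved with SLSQP from the equal-weight start with
  the analytic gradient (ftol 1e-12, the objective expressed as the
  quadratic form w'Aw − 2b'w + c). The solver's answer is then compared
  against every unit vector, the equal-weight point and the EWA point, and
  the best feasible candidate wins — a cheap guard against solver
  misbehaviour on degenerate (perfectly collinear) prediction matrices
  that also makes the dominance guarantee hold by construction even when
  SLSQP fails. The whole procedure is deterministic.
* **Average** uses wⱼ = 1/k.
* **EWA** uses wⱼ ∝ exp(−eⱼ). The error eⱼ is the learner's OOB RRMSE by
  default: a dimensionless ~0.1-scale quantity. Exponentiating raw kg/ha
  errors (~10³) underflows every weight except the argmin's, degenerating
  EWA into "pick the best learner"; the scale of eⱼ is therefore exposed
  as a parameter (`rrmse` or `rmse_scaled` = RMSE/SD(y)). The softmax is
  computed shift-invariantly from e − min(e).
* **Stacked generalization** fits a second-level learner (linear, LASSO,
  random forest or LightGBM) on the OOB prediction columns. Whether the
  second level should itself be tuned per fold is left open; it reuses
  family defaults.

After weights or the stacking map are learned from OOB, deployment-time
base learners are refitted on the full training panel.

## Base learners

OLS and LASSO implement the two written-out losses — residual sum of
squares, and RSS + λΣ|βⱼ| with the intercept unpenalized. LASSO is solved
by coordinate descent (scikit-learn, tol 1e-7, max 10,000 sweeps) with
α = λ/(2n) translating the penalized-RSS loss into scikit-learn's
per-sample objective; λ = 0 falls back to OLS, where the solution is
defined without a regularization path. The linear family refuses designs
with ≥ as many features as rows and points the user at the LASSO or tree
families. Random forest, XGBoost and LightGBM plug in behind the same
contract with their seeds wired through; all default to single-threaded
operation so runs are reproducible core-for-core. Default hyperparameters
(e.g. 100–200 trees) are package choices; search spaces are expected to be
supplied per analysis.

## Metrics, aggregation, scenarios

RMSE, RRMSE (= RMSE / mean observed; reported as a fraction, printed as
percent), MBE (mean of prediction − observation; positive means
overestimation) and MDA. MDA compares the last evaluation year with the
previous year's *actuals* per location: a case is correct when
sign(y_t − y_{t−1}) = sign(ŷ_t − y_{t−1}), with exact zeros matching only
exact zeros. At district/state scale, truths and predictions are first
aggregated as harvested-area-weighted means per (unit, year) and MDA is
computed on the aggregated series — with correspondingly few data points,
so coarse-scale MDA is noisy by nature.

Partial-season scenarios drop weather columns with week > cutoff;
selection and tuning are re-run per scenario since the information set
changed. The default date→week map is June 1 ≈ 22, July 1 ≈ 26,
August 1 ≈ 31, September 1 ≈ 35, October 1 ≈ 40 (exposed as
configuration).

## Partial dependence and importance

PD of predictor f for feature x at grid value v is the mean prediction
over all training rows with x forced to v. The default grid is 20 equally
spaced quantiles of the feature's training distribution; the full training
set is used (no subsampling) since desk-scale panels make the pass cheap.
Because a convex-weighted ensemble is linear in its members' predictions,
its PD curve equals the same convex combination of member PD curves; the
package computes it both ways and the tests require agreement to 1e-12.
Importance is the sample standard deviation (divisor k−1) of the ensemble
PD values over the grid — zero for a flat curve, in response units
otherwise, computed on the model's (scaled) input space.

## Synthetic panels

The generator emulates: a per-location linear yield trend with slope drawn
uniformly from 32–189 kg/ha/yr; weekly weather as a per-variable seasonal
sinusoid plus a location offset plus iid weekly noise (seven variables by
default, matching a Daymet-style feed); nine static soil features; a
logistic cumulative planting-progress curve and a static plant population;
log-uniform harvested areas constant over years; optional redundant
feature pairs (affine copies with 1 % jitter, |r| > 0.95 by construction);
and optional additive linear effects of named features on the response,
plus Gaussian noise (default SD 600 kg/ha on a base yield of 8,000 kg/ha —
a county-yield noise level the source data never pins down, so it is a
free parameter). Randomness is hierarchical: the global seed spawns one
substream per location, so adding locations never perturbs existing rows;
state and district labels are assigned by modulo so they are stable too.

What the generator does **not** emulate: spatial correlation between
neighbouring counties, year-level weather shocks shared across locations,
heavy-tailed yield losses (drought, flood years), missing county-years,
and any nonlinear weather–yield response unless injected through a custom
effect. Passing tests therefore establish the *mechanics* of the pipeline
— no leakage, correct optimization, exact identities, sane selection — not
that any particular accuracy level will transfer to real panels.

## Problem sizes and numerical conventions

The test suite and acceptance script run on panels of 5–250 locations and
16–19 years — large enough to give ≥ 2,000 OOB rows where weight-recovery
properties are asserted, small enough for the whole suite to run in tens
of seconds. Degenerate inputs are rejected loudly rather than coerced:
empty metric inputs, zero mean in RRMSE, all-zero area weights within a
group, single-year locations for trend fitting, correlation thresholds
outside (0, 1], weather cutoffs before the first observed week. Ties are
deterministic everywhere: column order in selection, alphabetical order in
importance ranking.

## Known limitations

* The simplex QP is solved to ftol 1e-12; objectives closer than ~1e-12
  between candidate vertices may pick either (predictions are unaffected
  at that scale).
* Stacked ensembles inherit the non-IID caveat: blocked OOB reduces but
  does not remove the mismatch between OOB rows and future test rows.
* EWA's error scale is a genuine modelling choice, not a derived quantity;
  results can be sensitive to it when learners are near-tied.
* The expert filter identifies weekly management columns by their week
  tag; management features without a week tag (plant population) are never
  filtered.
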