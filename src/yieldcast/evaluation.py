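"""Forecast metrics, multi-scale aggregation and scenario experiments.

Metrics
-------
RMSE (kg/ha), RRMSE (RMSE / mean observed, a fraction), MBE (mean of
prediction - observation; positive = overestimation) and MDA (mean
directional accuracy: the fraction of locations where the forecast moves in
the same direction as the actual relative to the prior year's actual).

Scales
------
County-level forecasts are aggregated to agricultural-district and state
level as harvested-area-weighted means, applied identically to truths and
predictions before metrics are computed at the coarse scale.

Scenarios
---------
Partial in-season weather knowledge is modelled by dropping weather columns
with week-of-year beyond a cutoff; the whole pipeline (trend features,
scaling, optional selection and tuning, OOB, ensembles) is re-run per
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import learners as learners_mod
from .ensembles import fit_stacked
from .learners import LearnerSpec
from .panel import PanelDataset, split_by_year
from .preprocess import (
    PanelMinMaxScaler,
    TrendFeaturizer,
    correlation_filter,
    expert_filter,
    permutation_select,
)
from .temporal import generate_oob, make_walk_forward_plan, tune

# ---------------------------------------------------------------------------
# metrics


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean squared error, same units as the response."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rrmse(y, yhat) -> float:
    """RMSE normalized by the mean observed value (a fraction)."""
    y, yhat = _check_pair(y, yhat)
    m = y.mean()
    if m == 0:
        raise ValueError("mean of observations is zero; RRMSE undefined")
    return rmse(y, yhat) / m


def mbe(y, yhat) -> float:
    """Mean bias error, mean(prediction - observation); positive = overestimate."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(yhat - y))


def mda(y_prev, y_curr, yhat_curr) -> float:
    """Mean directional accuracy against the prior year's actuals.

    A case counts as correct when sign(y_curr - y_prev) equals
    sign(yhat_curr - y_prev); exact zero differences match only another
    exact zero.
    """
    y_prev = np.asarray(y_prev, dtype=float)
    y_curr, yhat_curr = _check_pair(y_curr, yhat_curr)
    if y_prev.shape != y_curr.shape:
        raise ValueError("y_prev must align with y_curr")
    return float(np.mean(np.sign(y_curr - y_prev) == np.sign(yhat_curr - y_prev)))


def aggregate(values, areas, groups) -> pd.Series:
    """Harvested-area-weighted mean of county values per group.

    ``values``, ``areas`` and ``groups`` are aligned sequences; the result is
    indexed by group label.  Weights must be nonnegative and not all zero
    within any group.
    """
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    groups = np.asarray(groups)
    if (areas < 0).any():
        raise ValueError("harvested areas must be nonnegative")
    df = pd.DataFrame({"v": values, "a": areas, "g": groups})
    sums = df.groupby("g", sort=True).apply(
        lambda d: pd.Series({"num": (d.v * d.a).sum(), "den": d.a.sum()}),
        include_groups=False,
    )
    if (sums["den"] == 0).any():
        bad = sums.index[sums["den"] == 0].tolist()
        raise ValueError(f"all-zero harvested area in group(s) {bad}")
    return sums["num"] / sums["den"]


# ---------------------------------------------------------------------------
# weather cutoff scenarios


def apply_weather_cutoff(data: PanelDataset, cutoff_week: int) -> PanelDataset:
    """Drop weather columns with week beyond the cutoff (unknown future
    weather); all non-weather columns are retained."""
    weather_weeks = [
        m.week for m in data.feature_meta.values() if m.group == "weather"
    ]
    if not weather_weeks:
        raise ValueError("panel has no weather features")
    if cutoff_week < min(weather_weeks):
        raise ValueError(
            f"cutoff week {cutoff_week} precedes the first weather week "
            f"{min(weather_weeks)}; no weather would remain"
        )
    kept = [
        name
        for name, m in data.feature_meta.items()
        if m.group != "weather" or m.week <= cutoff_week
    ]
    return data.select_features(kept)


@dataclass(frozen=True)
class ScenarioConfig:
    """One partial-knowledge evaluation scenario.

    ``weather_cutoff_week=None`` means complete in-season weather knowledge.
    """

    name: str
    weather_cutoff_week: int | None = None
    scales: tuple[str, ...] = ("county", "district", "state")


#: approximate first-of-month to week-of-year map used for cutoff scenarios
MONTH_START_WEEKS: Mapping[str, int] = {
    "june": 22,
    "july": 26,
    "august": 31,
    "september": 35,
    "october": 40,
}


# ---------------------------------------------------------------------------
# experiment driver


SCALE_GROUP_COLUMN = {"county": "location_id", "district": "district", "state": "state"}


def _metrics_at_scale(
    test_frame: pd.DataFrame, pred: np.ndarray, scale: str
) -> dict[str, float]:
    """Pooled test metrics at one scale plus last-vs-previous-year MDA."""
    df = test_frame[["location_id", "district", "state", "year",
                     "response", "harvested_area"]].copy()
    df["pred"] = pred
    group_col = SCALE_GROUP_COLUMN[scale]
    if scale == "county":
        y, yhat = df["response"].to_numpy(), df["pred"].to_numpy()
        keyed = df.set_index([group_col, "year"])
        truth = keyed["response"]
        predicted = keyed["pred"]
    else:
        rows = []
        for year, g in df.groupby("year"):
            t = aggregate(g["response"], g["harvested_area"], g[group_col])
            p = aggregate(g["pred"], g["harvested_area"], g[group_col])
            for unit in t.index:
                rows.append((unit, year, t[unit], p[unit]))
        agg = pd.DataFrame(rows, columns=[group_col, "year", "response", "pred"])
        y, yhat = agg["response"].to_numpy(), agg["pred"].to_numpy()
        keyed = agg.set_index([group_col, "year"])
        truth = keyed["response"]
        predicted = keyed["pred"]

    years = sorted(df["year"].unique())
    out = {
        "n": int(len(y)),
        "rmse": rmse(y, yhat),
        "rrmse": rrmse(y, yhat),
        "mbe": mbe(y, yhat),
        "mda": np.nan,
        "mda_years": None,
    }
    # directional accuracy: last test year against the previous year's actuals
    if len(years) >= 2:
        last, prev = years[-1], years[-2]
        units = sorted(
            set(truth.loc[(slice(None), last)].index)
            & set(truth.loc[(slice(None), prev)].index)
        )
        if units:
            out["mda"] = mda(
                truth.loc[[(u, prev) for u in units]].to_numpy(),
                truth.loc[[(u, last) for u in units]].to_numpy(),
                predicted.loc[[(u, last) for u in units]].to_numpy(),
            )
            out["mda_years"] = f"{last}-{prev}"
    return out


@dataclass
class ExperimentConfig:
    """Knobs of :func:`run_experiment` beyond the scenario list."""

    window_size: int = 8
    first_test_year: int | None = None  # default: last 3 years held out
    ensemble_methods: tuple[str, ...] = ("optimized", "average", "ewa")
    stacked_families: tuple[str, ...] = ()
    run_selection: bool = False
    growing_season: tuple[int, int] = (14, 44)
    planting_window_start: int = 14
    n_keep: int = 80
    corr_threshold: float = 0.9
    tune_spaces: Mapping[str, Mapping[str, Sequence]] = field(default_factory=dict)
    tune_budget: int = 10


def run_experiment(
    panel: PanelDataset,
    scenarios: Sequence[ScenarioConfig],
    learner_specs: Sequence[LearnerSpec],
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end scenario evaluation; fully deterministic given ``seed``.

    Per scenario: weather cutoff -> year split -> trend features -> scaling
    -> optional three-stage selection -> optional tuning -> blocked OOB ->
    ensembles -> test-year forecasts -> metrics at every requested scale.

    Returns a tidy MetricReport frame with one row per
    (scenario, model, scale).
    """
    config = config or ExperimentConfig()
    rows = []
    for scenario in scenarios:
        data = panel
        if scenario.weather_cutoff_week is not None:
            data = apply_weather_cutoff(data, scenario.weather_cutoff_week)

        first_test = config.first_test_year
        if first_test is None:
            first_test = int(data.years.max()) - 2
        train, test = split_by_year(data, first_test)

        trender = TrendFeaturizer().fit(train)
        train = trender.transform(train)
        test = trender.transform(test)
        scaler = PanelMinMaxScaler().fit(train)
        train = scaler.transform(train)
        test = scaler.transform(test)

        if config.run_selection:
            train, _ = expert_filter(
                train, config.growing_season, config.planting_window_start
            )
            n_keep = min(config.n_keep, len(train.feature_meta))
            train, _ = permutation_select(train, n_keep=n_keep, seed=seed)
            train, _ = correlation_filter(train, threshold=config.corr_threshold)
            test = test.select_features(train.features)

        plan = make_walk_forward_plan(train.years, config.window_size)

        specs = []
        for spec in learner_specs:
            space = config.tune_spaces.get(spec.name)
            if space:
                best, _ = tune(
                    spec, space, train, plan,
                    budget=config.tune_budget, strategy="random", seed=seed,
                )
                spec = LearnerSpec(
                    name=spec.name, family=spec.family,
                    hyperparameters={**spec.hyperparameters, **best}, seed=spec.seed,
                )
            specs.append(spec)

        oob = generate_oob(specs, train, plan)
        fitted = [learners_mod.fit(s, train.X, train.y) for s in specs]
        base_matrix_test = np.column_stack([m.predict(test.X) for m in fitted])

        model_preds: dict[str, np.ndarray] = {
            s.name: base_matrix_test[:, j] for j, s in enumerate(specs)
        }
        from . import ensembles as ens_mod

        for method in config.ensemble_methods:
            if method == "optimized":
                weights = ens_mod.optimize_weights(oob)
            elif method == "average":
                weights = ens_mod.average_weights(oob.k, oob.learner_names)
            elif method == "ewa":
                weights = ens_mod.ewa_weights(oob)
            else:
                raise ValueError(f"unknown ensemble method {method!r}")
            model_preds[f"{method}_ensemble"] = ens_mod.predict_weighted(
                weights, base_matrix_test
            )
        for family in config.stacked_families:
            second = LearnerSpec(name=f"stack_{family}", family=family, seed=seed)
            stacked = fit_stacked(oob, second, base_specs=specs, train=train)
            model_preds[f"stacked_{family}"] = stacked.predict(test.X)

        for model_name, pred in model_preds.items():
            for scale in scenario.scales:
                m = _metrics_at_scale(test.frame, pred, scale)
                rows.append({"scenario": scenario.name, "model": model_name,
                             "scale": scale, **m})
    return pd.DataFrame(rows)
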