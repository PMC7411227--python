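"""Pre-processing fitted on training rows only.

Three concerns live here, in the order the pipeline applies them:

1. **Trend features** — two constructed covariates capturing the
   technology-driven yearly yield increase: ``yield_trend`` (per-location OLS
   of yield on calendar year, extrapolated to test years) and ``yield_avg``
   (per-state training-year mean yield; for test years the last training
   year's state mean compounded by the mean relative year-on-year increment).
2. **Min-max scaling** — every feature mapped to [0, 1] using training
   min/max; test values may fall outside the unit interval.
3. **Three-stage feature selection** — an expert filter on week tags, a
   permutation-importance top-k screen using a random-forest-style learner,
   and a greedy Pearson-correlation filter.  Trend-constructed features are
   force-retained throughout and never consume selection slots.

All transformers follow the sklearn estimator protocol (fit/transform,
get_params/set_params, trailing-underscore fitted state) but operate on
:class:`~yieldcast.panel.PanelDataset` so feature metadata survives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.inspection import permutation_importance

from . import learners
from .learners import LearnerSpec
from .panel import FeatureInfo, PanelDataset

# ---------------------------------------------------------------------------
# selection report


@dataclass
class SelectionStage:
    name: str
    n_before: int
    n_after: int
    removed: list[str]
    details: dict[str, Any] = dc_field(default_factory=dict)


@dataclass
class SelectionReport:
    """Ordered record of the selection stages applied to one panel."""

    stages: list[SelectionStage] = dc_field(default_factory=list)

    def add(self, stage: SelectionStage) -> None:
        self.stages.append(stage)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "n_before": s.n_before,
                    "n_after": s.n_after,
                    "removed": s.removed,
                    "details": s.details,
                }
                for s in self.stages
            ]
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=float))


# ---------------------------------------------------------------------------
# min-max scaling


class PanelMinMaxScaler(BaseEstimator):
    """Scale every feature to [0, 1] by training min/max.

    Constant training features map to 0 by convention.  Applied to unseen
    rows the output may leave [0, 1]; that is intentional (no clipping), so
    a warm test year is visibly warmer than anything in training.
    """

    def fit(self, panel: PanelDataset) -> "PanelMinMaxScaler":
        if panel.n_rows == 0:
            raise ValueError("cannot fit scaler on an empty panel")
        X = panel.X
        for col in X.columns:
            if not pd.api.types.is_numeric_dtype(X[col]):
                raise ValueError(f"feature {col!r} is not numeric")
        self.feature_names_ = list(X.columns)
        self.min_ = X.min(axis=0).to_numpy(dtype=float)
        self.max_ = X.max(axis=0).to_numpy(dtype=float)
        return self

    def transform(self, panel: PanelDataset) -> PanelDataset:
        if list(panel.features) != self.feature_names_:
            raise ValueError("panel features differ from those the scaler saw at fit")
        span = self.max_ - self.min_
        safe = np.where(span == 0, 1.0, span)  # constant features -> 0
        out = panel.frame.copy()
        out[self.feature_names_] = (
            out[self.feature_names_].to_numpy(dtype=float) - self.min_
        ) / safe
        return PanelDataset(out, panel.feature_meta, validate=False)

    def fit_transform(self, panel: PanelDataset) -> PanelDataset:
        return self.fit(panel).transform(panel)


def fit_minmax(train: PanelDataset) -> PanelMinMaxScaler:
    """Fit the [0, 1] scaler on training rows only."""
    return PanelMinMaxScaler().fit(train)


# ---------------------------------------------------------------------------
# trend features


class TrendFeaturizer(BaseEstimator):
    """Construct ``yield_trend`` and ``yield_avg`` from training years.

    ``yield_trend`` for location *i* is the fitted value b0_i + b1_i * YEAR of
    a per-location OLS of response on calendar year; test years extrapolate
    the same line.  ``yield_avg`` for a training row is its state's training
    mean yield in that year; for a test year ``t`` it is the last training
    year's state mean compounded by the mean relative year-on-year increment
    g: baseline * (1 + g)^(t - last_training_year).  At t = last training
    year the compound formula reproduces the baseline exactly, so the two
    regimes join continuously.
    """

    def fit(self, train: PanelDataset) -> "TrendFeaturizer":
        df = train.frame
        self.coef_: dict[str, tuple[float, float]] = {}
        for loc, g in df.groupby("location_id", sort=True):
            yrs = g["year"].to_numpy(dtype=float)
            if len(np.unique(yrs)) < 2:
                raise ValueError(
                    f"location {loc!r} has a single training year; trend slope undefined"
                )
            b1, b0 = np.polyfit(yrs, g["response"].to_numpy(dtype=float), 1)
            self.coef_[loc] = (float(b0), float(b1))

        self.state_year_mean_: dict[tuple[str, int], float] = {}
        self.baseline_: dict[str, float] = {}
        self.growth_: dict[str, float] = {}
        self.last_train_year_ = int(df["year"].max())
        for state, g in df.groupby("state", sort=True):
            means = g.groupby("year")["response"].mean().sort_index()
            if len(means) < 2:
                raise ValueError(
                    f"state {state!r} has a single training year; growth undefined"
                )
            for year, m in means.items():
                self.state_year_mean_[(state, int(year))] = float(m)
            rel = means.to_numpy()[1:] / means.to_numpy()[:-1] - 1.0
            self.baseline_[state] = float(means.iloc[-1])
            self.growth_[state] = float(rel.mean())
        return self

    def transform(self, data: PanelDataset) -> PanelDataset:
        df = data.frame
        unseen_loc = set(df["location_id"]) - set(self.coef_)
        if unseen_loc:
            raise ValueError(f"locations never seen in training: {sorted(unseen_loc)}")
        unseen_state = set(df["state"]) - set(self.baseline_)
        if unseen_state:
            raise ValueError(f"states never seen in training: {sorted(unseen_state)}")

        b = np.array([self.coef_[loc] for loc in df["location_id"]])
        yield_trend = b[:, 0] + b[:, 1] * df["year"].to_numpy(dtype=float)

        yield_avg = np.empty(len(df))
        for i, (state, year) in enumerate(zip(df["state"], df["year"])):
            year = int(year)
            if year <= self.last_train_year_:
                try:
                    yield_avg[i] = self.state_year_mean_[(state, year)]
                except KeyError:
                    raise ValueError(
                        f"no training mean for state {state!r}, year {year}"
                    ) from None
            else:
                horizon = year - self.last_train_year_
                yield_avg[i] = self.baseline_[state] * (1.0 + self.growth_[state]) ** horizon

        out = data.with_feature("yield_trend", yield_trend, FeatureInfo("trend"))
        out = out.with_feature("yield_avg", yield_avg, FeatureInfo("trend"))
        return out

    def fit_transform(self, train: PanelDataset) -> PanelDataset:
        return self.fit(train).transform(train)


def fit_trend_features(train: PanelDataset) -> TrendFeaturizer:
    return TrendFeaturizer().fit(train)


def apply_trend_features(model: TrendFeaturizer, data: PanelDataset) -> PanelDataset:
    """Append the two trend columns; train vs test regime is inferred per row
    from its year relative to the fitted last training year."""
    return model.transform(data)


# ---------------------------------------------------------------------------
# stage 1: expert filter


def expert_filter(
    data: PanelDataset,
    growing_season: tuple[int, int] = (14, 44),
    planting_window_start: int = 14,
) -> tuple[PanelDataset, SelectionReport]:
    """Drop weather weeks outside the growing season and pre-window planting
    progress; soil, trend and static management columns are untouched."""
    first, last = growing_season
    removed: list[str] = []
    for name, info in data.feature_meta.items():
        if info.group == "weather" and not (first <= info.week <= last):
            removed.append(name)
        elif info.group == "management" and info.week is not None and info.week < planting_window_start:
            removed.append(name)
    kept = [f for f in data.feature_meta if f not in set(removed)]
    report = SelectionReport()
    report.add(
        SelectionStage(
            name="expert_filter",
            n_before=len(data.feature_meta),
            n_after=len(kept),
            removed=removed,
            details={"growing_season": list(growing_season),
                     "planting_window_start": planting_window_start},
        )
    )
    return data.select_features(kept), report


from sklearn.base import RegressorMixin


class _ScoringAdapter(RegressorMixin, BaseEstimator):
    """Minimal sklearn-estimator facade over a FittedLearner for scorers."""

    def __init__(self, fitted: learners.FittedLearner):
        self._fitted = fitted
        self.is_fitted_ = True

    def fit(self, X, y):  # pragma: no cover - never refit during scoring
        raise RuntimeError("adapter is scoring-only")

    def predict(self, X):
        return self._fitted.predict(X)


# ---------------------------------------------------------------------------
# stage 2: permutation-importance screen


def permutation_select(
    train: PanelDataset,
    learner: LearnerSpec | None = None,
    n_keep: int = 80,
    n_repeats: int = 5,
    seed: int = 0,
) -> tuple[PanelDataset, SelectionReport]:
    """Keep the ``n_keep`` features with highest permutation importance.

    Importance of a feature is the mean increase in training-set MSE over
    ``n_repeats`` seeded permutations of its column.  Trend-constructed
    features are force-retained and do not consume ``n_keep`` slots.  Ties
    are broken by column order.
    """
    if learner is None:
        learner = LearnerSpec(name="selector_rf", family="random_forest",
                              hyperparameters={"n_estimators": 100}, seed=seed)
    candidates = [f for f, m in train.feature_meta.items() if m.group != "trend"]
    forced = [f for f, m in train.feature_meta.items() if m.group == "trend"]
    if n_keep > len(train.feature_meta):
        raise ValueError(
            f"n_keep={n_keep} exceeds feature count {len(train.feature_meta)}"
        )

    fitted = learners.fit(learner, train.X, train.y)
    result = permutation_importance(
        _ScoringAdapter(fitted),
        train.X,
        train.y.to_numpy(dtype=float),
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=seed,
    )
    scores = dict(zip(train.features, result.importances_mean))

    cand_scores = np.array([scores[f] for f in candidates])
    # stable sort on negated scores: equal importances keep column order
    order = np.argsort(-cand_scores, kind="stable")
    top = {candidates[i] for i in order[: min(n_keep, len(candidates))]}
    kept = [f for f in train.feature_meta if f in top or f in set(forced)]

    report = SelectionReport()
    report.add(
        SelectionStage(
            name="permutation_importance",
            n_before=len(train.feature_meta),
            n_after=len(kept),
            removed=[f for f in train.feature_meta if f not in set(kept)],
            details={
                "scores": {f: float(scores[f]) for f in train.features},
                "forced_trend_features": forced,
                "n_keep": n_keep,
                "n_repeats": n_repeats,
            },
        )
    )
    return train.select_features(kept), report


# ---------------------------------------------------------------------------
# stage 3: correlation filter


def correlation_filter(
    train: PanelDataset,
    threshold: float = 0.9,
    protected_groups: frozenset[str] = frozenset({"trend"}),
) -> tuple[PanelDataset, SelectionReport]:
    """Greedy Pearson de-duplication on training rows.

    Features are scanned in column order; one is dropped when its absolute
    correlation with an already-retained feature exceeds ``threshold`` (the
    earlier column wins).  Features in ``protected_groups`` are always
    retained.  Constant columns have undefined correlation: they are retained
    and flagged rather than silently dropped, since a constant feature
    usually signals a data bug worth surfacing.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if train.n_rows < 2:
        raise ValueError("need at least 2 rows to compute correlations")

    feats = train.features
    X = train.X.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constants correlate with nothing

    retained_idx: list[int] = []
    dropped: list[str] = []
    pairs: list[dict] = []
    protected = {
        i for i, f in enumerate(feats) if train.feature_meta[f].group in protected_groups
    }
    for i in range(len(feats)):
        if i in protected or constant[i]:
            retained_idx.append(i)
            continue
        partner = None
        for j in retained_idx:
            if abs(corr[i, j]) > threshold:
                partner = j
                break
        if partner is None:
            retained_idx.append(i)
        else:
            dropped.append(feats[i])
            pairs.append(
                {"dropped": feats[i], "kept": feats[partner], "r": float(corr[i, partner])}
            )

    kept = [feats[i] for i in retained_idx]
    report = SelectionReport()
    report.add(
        SelectionStage(
            name="correlation_filter",
            n_before=len(feats),
            n_after=len(kept),
            removed=dropped,
            details={
                "threshold": threshold,
                "pairs": pairs,
                "constant_features": [f for f, c in zip(feats, constant) if c],
            },
        )
    )
    return train.select_features(kept), report
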