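"""Partial dependence and PDP-dispersion feature importance.

The partial dependence of a fitted predictor f on feature x_K at value v is
the average prediction over the training rows with x_K forced to v:

    PD_K(v) = (1/n) sum_i f(v, x_{K'}^{(i)})

Because a convex-weighted ensemble prediction is linear in its base
learners' predictions, its PD curve is exactly the same convex combination
of the base learners' PD curves — the identity this module both exploits
(``ensemble_pdp``) and verifies in its tests.

Feature importance is the sample standard deviation (divisor k-1) of the
ensemble PD values over the grid: a flat curve scores zero, a steep one
scores in response units (kg/ha for yield panels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .ensembles import EnsembleWeights
from .panel import PanelDataset


class Predictor(Protocol):
    def predict(self, X: pd.DataFrame) -> np.ndarray: ...


@dataclass
class PDPCurve:
    """Partial-dependence estimates for one feature over a common grid."""

    feature: str
    grid: np.ndarray
    values: np.ndarray  # ensemble (or single-model) PD per grid point
    per_learner: dict[str, np.ndarray] = field(default_factory=dict)
    n_train: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and PD values must share length")
        for name, v in self.per_learner.items():
            if np.asarray(v).shape != self.grid.shape:
                raise ValueError(f"per-learner curve {name!r} length mismatch")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"feature": self.feature, "grid_value": self.grid,
                            "pd": self.values})
        for name, v in self.per_learner.items():
            out[f"pd_{name}"] = np.asarray(v, dtype=float)
        return out


def make_grid(train: PanelDataset, feature: str, k: int = 20) -> np.ndarray:
    """Default grid policy: k equally spaced quantiles of the training
    distribution of the feature (collapses duplicates for near-constant
    features)."""
    if feature not in train.feature_meta:
        raise KeyError(f"unknown feature {feature!r}")
    x = train.frame[feature].to_numpy(dtype=float)
    qs = np.linspace(0.0, 1.0, k)
    return np.unique(np.quantile(x, qs))


def pdp(
    model: Predictor,
    train: PanelDataset,
    feature: str,
    grid: Sequence[float] | None = None,
    k: int = 20,
) -> PDPCurve:
    """Estimate the PD curve of ``model`` for ``feature`` over ``grid``.

    For every grid value the feature column of the whole training table is
    replaced by that value, the model predicts, and predictions are averaged.
    No subsampling: desk-scale panels make the full pass affordable.
    """
    if feature not in train.feature_meta:
        raise KeyError(f"unknown feature {feature!r}")
    if grid is None:
        grid = make_grid(train, feature, k)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("grid needs at least 2 values")
    X = train.X.copy()
    values = np.empty(grid.size)
    for i, v in enumerate(grid):
        X[feature] = v
        values[i] = float(np.mean(model.predict(X)))
    return PDPCurve(feature=feature, grid=grid, values=values, n_train=train.n_rows)


def ensemble_pdp(
    weights: EnsembleWeights, base_curves: Sequence[PDPCurve]
) -> PDPCurve:
    """Combine base-learner PD curves with the ensemble weights.

    Pointwise w-weighted average; identical (to numerical precision) to
    running :func:`pdp` on the weighted-ensemble predictor directly.
    """
    if len(base_curves) != len(weights.weights):
        raise ValueError("need one curve per ensemble member")
    grid = base_curves[0].grid
    feature = base_curves[0].feature
    for c in base_curves[1:]:
        if c.grid.shape != grid.shape or not np.array_equal(c.grid, grid):
            raise ValueError("all base curves must share the same grid")
        if c.feature != feature:
            raise ValueError("all base curves must describe the same feature")
    stacked = np.column_stack([c.values for c in base_curves])
    combined = stacked @ weights.w
    return PDPCurve(
        feature=feature,
        grid=grid,
        values=combined,
        per_learner={
            name: c.values for name, c in zip(weights.learner_names, base_curves)
        },
        n_train=base_curves[0].n_train,
    )


def feature_importance(curve: PDPCurve) -> float:
    """Sample standard deviation (divisor k-1) of the PD values."""
    if curve.grid.size < 2:
        raise ValueError("importance needs a grid of at least 2 values")
    return float(np.std(curve.values, ddof=1))


@dataclass
class ImportanceTable:
    """Features ranked by PDP dispersion, descending; ties alphabetical."""

    frame: pd.DataFrame  # columns: rank, feature, week, importance

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def rank_features(
    model: Predictor,
    train: PanelDataset,
    features: Sequence[str] | None = None,
    k: int = 20,
) -> ImportanceTable:
    """PD-dispersion importance for every requested feature.

    Importance is in response units; the table is sorted descending with
    alphabetical tie-breaking and 1-based ranks.
    """
    features = list(features) if features is not None else train.features
    if not features:
        raise ValueError("empty feature list")
    rows = []
    for feat in features:
        try:
            curve = pdp(model, train, feat, k=k)
            imp = feature_importance(curve)
        except Exception as exc:
            raise RuntimeError(f"importance failed for feature {feat!r}") from exc
        rows.append(
            {"feature": feat, "week": train.feature_meta[feat].week, "importance": imp}
        )
    frame = (
        pd.DataFrame(rows)
        .sort_values(["importance", "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return ImportanceTable(frame)


class WeightedPredictor:
    """Convex combination of fitted base learners as a plain predictor.

    Convenience for computing ensemble PDPs directly (the slow route the
    ensemble-PDP identity is checked against).
    """

    def __init__(self, weights: EnsembleWeights, fitted_learners: Sequence):
        if len(fitted_learners) != len(weights.weights):
            raise ValueError("one fitted learner per weight required")
        self.weights = weights
        self.fitted_learners = list(fitted_learners)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        P = np.column_stack([m.predict(X) for m in self.fitted_learners])
        return P @ self.weights.w
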