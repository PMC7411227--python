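"""Walk-forward splits, blocked sequential out-of-bag prediction, tuning.

Yield panels are not IID: rows from the same year share a weather draw and
rows from the same county share soil, so random k-fold CV leaks the future
into the past.  Everything here therefore slides forward in time.  A
:class:`SplitPlan` trains on a fixed window of ``window_size`` consecutive
years (8 by default) and validates on the following year, advancing one year
per fold until the final training year serves as validation.  Running every
base learner over that plan yields the blocked sequential out-of-bag (OOB)
matrix: one prediction column per learner, aligned to true responses, with
the first ``window_size`` years never appearing as validation rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import learners
from .learners import LearnerSpec
from .panel import PanelDataset


@dataclass(frozen=True)
class SplitPlan:
    """Ordered walk-forward folds of (training years, validation year)."""

    folds: tuple[tuple[tuple[int, ...], int], ...]
    window_size: int

    def __post_init__(self) -> None:
        prev_val = None
        for train_years, val_year in self.folds:
            if len(train_years) != self.window_size:
                raise ValueError("every fold must train on window_size years")
            if max(train_years) >= val_year:
                raise ValueError(
                    f"fold validating {val_year} trains on a year >= {val_year}"
                )
            if prev_val is not None and val_year != prev_val + 1:
                raise ValueError("validation years must be strictly consecutive")
            prev_val = val_year

    @property
    def validation_years(self) -> list[int]:
        return [v for _, v in self.folds]

    def __len__(self) -> int:
        return len(self.folds)


def make_walk_forward_plan(train_years: Sequence[int], window_size: int = 8) -> SplitPlan:
    """Slide a ``window_size``-year training block one year at a time.

    Years must be contiguous; the plan has ``len(train_years) - window_size``
    folds, the last validating on the final training year.
    """
    years = sorted(int(y) for y in train_years)
    if len(years) != len(set(years)):
        raise ValueError("duplicate years")
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        raise ValueError(f"training years must be contiguous, got {years}")
    if len(years) <= window_size:
        raise ValueError(
            f"need more than window_size={window_size} years, got {len(years)}"
        )
    folds = []
    for f in range(len(years) - window_size):
        folds.append((tuple(years[f : f + window_size]), years[f + window_size]))
    return SplitPlan(folds=tuple(folds), window_size=window_size)


class OOBMatrix:
    """Out-of-bag predictions aligned to true responses.

    ``frame`` columns: location_id, year, fold, y_true, then one prediction
    column per base learner (in learner order).
    """

    META_COLS = ("location_id", "year", "fold", "y_true")

    def __init__(self, frame: pd.DataFrame, learner_names: Sequence[str]):
        self.frame = frame.reset_index(drop=True)
        self.learner_names = list(learner_names)
        missing = [c for c in (*self.META_COLS, *self.learner_names) if c not in frame.columns]
        if missing:
            raise ValueError(f"OOB matrix missing columns {missing}")
        if self.frame[list(self.learner_names)].isna().any().any():
            raise ValueError("OOB matrix has missing predictions")

    @property
    def y(self) -> np.ndarray:
        return self.frame["y_true"].to_numpy(dtype=float)

    @property
    def predictions(self) -> np.ndarray:
        """n x k matrix of OOB predictions, one column per learner."""
        return self.frame[self.learner_names].to_numpy(dtype=float)

    @property
    def k(self) -> int:
        return len(self.learner_names)

    def __len__(self) -> int:
        return len(self.frame)

    def learner_mse(self) -> dict[str, float]:
        y = self.y
        return {
            name: float(np.mean((y - self.frame[name].to_numpy(dtype=float)) ** 2))
            for name in self.learner_names
        }


def generate_oob(
    specs: Sequence[LearnerSpec],
    train: PanelDataset,
    plan: SplitPlan,
) -> OOBMatrix:
    """Blocked sequential OOB generation.

    For each fold every learner is fitted afresh on the fold's training-year
    rows and predicts the validation-year rows; no model ever sees a year at
    or after the one it predicts.
    """
    if not specs:
        raise ValueError("need at least one learner")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("learner names must be unique")
    panel_years = set(int(y) for y in train.years)
    plan_years = set(y for tr, v in plan.folds for y in (*tr, v))
    missing_years = plan_years - panel_years
    if missing_years:
        raise ValueError(f"plan references years absent from panel: {sorted(missing_years)}")

    pieces = []
    for fold_id, (train_years, val_year) in enumerate(plan.folds):
        fit_rows = train.rows_in_years(train_years)
        val_rows = train.rows_in_years([val_year])
        piece = val_rows.frame[["location_id", "year"]].copy()
        piece["fold"] = fold_id
        piece["y_true"] = val_rows.y.to_numpy(dtype=float)
        for spec in specs:
            try:
                fitted = learners.fit(spec, fit_rows.X, fit_rows.y)
                piece[spec.name] = fitted.predict(val_rows.X)
            except Exception as exc:
                raise RuntimeError(
                    f"learner {spec.name!r} failed on fold {fold_id} "
                    f"(train {train_years[0]}-{train_years[-1]}, validate {val_year})"
                ) from exc
        pieces.append(piece)
    frame = pd.concat(pieces, ignore_index=True)
    return OOBMatrix(frame, names)


def cv_mse(spec: LearnerSpec, train: PanelDataset, plan: SplitPlan) -> float:
    """Mean validation MSE of one learner across the plan's folds."""
    fold_mse = []
    for train_years, val_year in plan.folds:
        fit_rows = train.rows_in_years(train_years)
        val_rows = train.rows_in_years([val_year])
        fitted = learners.fit(spec, fit_rows.X, fit_rows.y)
        resid = val_rows.y.to_numpy(dtype=float) - fitted.predict(val_rows.X)
        fold_mse.append(float(np.mean(resid**2)))
    return float(np.mean(fold_mse))


def tune(
    base_spec: LearnerSpec,
    space: Mapping[str, Sequence[Any]],
    train: PanelDataset,
    plan: SplitPlan,
    budget: int = 20,
    strategy: str = "random",
    seed: int = 0,
    sampler: Callable[..., Mapping[str, Any]] | None = None,
) -> tuple[dict[str, Any], list[tuple[dict[str, Any], float]]]:
    """Hyperparameter search scored by walk-forward validation MSE.

    ``space`` maps hyperparameter name to a finite list of candidate values.
    ``strategy="random"`` is the built-in seeded sampler (deterministic given
    ``seed``); ``strategy="tpe"`` delegates candidate proposal to a
    user-supplied ``sampler(trial_index, rng, space, trace)`` callable so a
    Bayesian/TPE backend can plug in without being a hard dependency.

    Returns ``(best_params, trace)`` where ``trace`` is the evaluated
    (candidate, score) sequence in order.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("empty search space")
    if strategy not in ("random", "tpe"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "tpe" and sampler is None:
        raise ValueError(
            "strategy='tpe' needs a sampler backend; pass sampler=..., or use "
            "strategy='random' for the built-in seeded fallback"
        )

    rng = np.random.default_rng(seed)
    trace: list[tuple[dict[str, Any], float]] = []
    seen: set[tuple] = set()
    for t in range(budget):
        if sampler is not None:
            candidate = dict(sampler(t, rng, space, trace))
        else:
            candidate = {k: v[rng.integers(len(v))] for k, v in space.items()}
        key = tuple(sorted(candidate.items()))
        if key in seen and sampler is None:
            continue  # random search: skip duplicate draws, budget counts draws
        seen.add(key)
        spec = LearnerSpec(
            name=base_spec.name,
            family=base_spec.family,
            hyperparameters={**base_spec.hyperparameters, **candidate},
            seed=base_spec.seed,
        )
        trace.append((candidate, cv_mse(spec, train, plan)))
    best_params, _ = min(trace, key=lambda item: item[1])
    return dict(best_params), trace
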