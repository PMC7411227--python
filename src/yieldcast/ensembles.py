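"""Ensemble constructions over blocked out-of-bag predictions.

Four ways to combine k base learners, all consuming the same
:class:`~yieldcast.temporal.OOBMatrix`:

* **Optimized weighted ensemble** — weights minimize the OOB mean squared
  error over the probability simplex:

      min_w (1/n) sum_i (y_i - sum_j w_j yhat_ij)^2
      s.t.  sum_j w_j = 1,  w_j >= 0.

  This is a convex quadratic program; because every unit vector is feasible,
  the optimum never does worse (on OOB) than any single base learner, the
  equal-weight average, or the EWA weights.
* **Average ensemble** — w_j = 1/k.
* **Exponentially weighted average (EWA)** — w_j = exp(-e_j) / sum exp(-e_j)
  with e_j the learner's OOB error.  The error is measured as RRMSE by
  default: a dimensionless ~0.1-scale quantity, since exponentiating raw
  kg/ha errors (~1000) underflows to a degenerate argmax.
* **Stacked generalization** — a second-level learner fitted on the OOB
  prediction columns as inputs and the true responses as target.

After weights or the stacking map are learned from OOB, deployment-time base
learners are re-fitted on the full training panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from . import learners
from .learners import FittedLearner, LearnerSpec
from .panel import PanelDataset
from .temporal import OOBMatrix, SplitPlan, generate_oob, make_walk_forward_plan

STACKING_FAMILIES = ("linear", "lasso", "random_forest", "gbm_lgbm")


@dataclass(frozen=True)
class EnsembleWeights:
    """A point on the k-simplex plus provenance."""

    weights: tuple[float, ...]
    learner_names: tuple[str, ...]
    method: str
    oob_objective: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if len(w) != len(self.learner_names):
            raise ValueError("one weight per learner required")
        if (w < -1e-12).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    @property
    def w(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "weights": dict(zip(self.learner_names, map(float, self.weights))),
            "oob_mse": self.oob_objective,
        }


def _oob_objective(oob: OOBMatrix, w: np.ndarray) -> float:
    resid = oob.y - oob.predictions @ w
    return float(np.mean(resid**2))


def optimize_weights(oob: OOBMatrix) -> EnsembleWeights:
    """Solve the simplex-constrained OOB-MSE quadratic program.

    SLSQP with the analytic gradient, started from equal weights; the result
    is compared against every unit vector and the start point, and the best
    feasible point wins — a cheap guard against solver failure on degenerate
    (e.g. perfectly collinear) prediction matrices.  Deterministic.
    """
    if oob.k < 1:
        raise ValueError("need at least one learner column")
    if len(oob) < 1:
        raise ValueError("empty OOB matrix")
    Y = oob.predictions
    y = oob.y
    n, k = Y.shape
    # objective as a quadratic form: w'Aw - 2 b'w + c
    A = Y.T @ Y / n
    b = Y.T @ y / n
    c = float(y @ y) / n

    def fun(w):
        return float(w @ A @ w - 2.0 * b @ w + c)

    def jac(w):
        return 2.0 * (A @ w - b)

    w0 = np.full(k, 1.0 / k)
    res = minimize(
        fun,
        w0,
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    candidates = [np.eye(k)[j] for j in range(k)] + [w0]
    if y.mean() != 0:  # the EWA point is feasible too; keep it dominated
        e = np.sqrt(np.mean((y[:, None] - Y) ** 2, axis=0)) / y.mean()
        if np.isfinite(e).all():
            z = np.exp(-(e - e.min()))
            candidates.append(z / z.sum())
    if res.success and np.isfinite(res.x).all():
        w = np.clip(res.x, 0.0, None)
        w = w / w.sum()
        candidates.insert(0, w)
    best = min(candidates, key=fun)
    return EnsembleWeights(
        weights=tuple(float(x) for x in best),
        learner_names=tuple(oob.learner_names),
        method="optimized",
        oob_objective=fun(best),
    )


def average_weights(k: int, learner_names: Sequence[str] | None = None) -> EnsembleWeights:
    """Equal weights w_j = 1/k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    names = tuple(learner_names) if learner_names else tuple(f"m{j}" for j in range(k))
    if len(names) != k:
        raise ValueError("learner_names length must equal k")
    return EnsembleWeights(weights=(1.0 / k,) * k, learner_names=names, method="average")


def ewa_weights(oob: OOBMatrix, error_metric: str = "rrmse") -> EnsembleWeights:
    """Softmax of negated OOB errors: w_j = exp(-e_j) / sum_j exp(-e_j)."""
    if error_metric not in ("rrmse", "rmse_scaled"):
        raise ValueError(f"unknown error_metric {error_metric!r}")
    y = oob.y
    rmse = np.sqrt(np.mean((y[:, None] - oob.predictions) ** 2, axis=0))
    if error_metric == "rrmse":
        denom = y.mean()
        if denom == 0:
            raise ValueError("mean response is zero; RRMSE undefined")
    else:
        denom = y.std(ddof=1)
        if denom == 0:
            raise ValueError("constant response; scaled RMSE undefined")
    e = rmse / denom
    if not np.isfinite(e).all():
        raise ValueError("non-finite OOB error")
    z = np.exp(-(e - e.min()))  # shift-invariant softmax, avoids underflow
    w = z / z.sum()
    ew = EnsembleWeights(
        weights=tuple(float(x) for x in w),
        learner_names=tuple(oob.learner_names),
        method="ewa",
    )
    return EnsembleWeights(
        weights=ew.weights,
        learner_names=ew.learner_names,
        method="ewa",
        oob_objective=_oob_objective(oob, ew.w),
    )


def predict_weighted(weights: EnsembleWeights, base_predictions) -> np.ndarray:
    """Row-wise convex combination of base-learner predictions."""
    P = np.asarray(base_predictions, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(weights.weights):
        raise ValueError(
            f"prediction matrix must be n x {len(weights.weights)}, got {P.shape}"
        )
    return P @ weights.w


# ---------------------------------------------------------------------------
# estimator classes


class WeightedEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Convex-combination ensemble fitted by blocked walk-forward OOB.

    Parameters
    ----------
    base_specs
        Base-learner specifications; each is re-fitted per fold during OOB
        generation and once more on the full training panel for deployment.
    method
        ``"optimized"`` (simplex QP on OOB MSE), ``"average"`` or ``"ewa"``.
    window_size
        Training-window length (years) of the walk-forward plan.
    ewa_error_metric
        Error scale for the EWA softmax.

    Attributes
    ----------
    weights_ : EnsembleWeights
    oob_ : OOBMatrix
    fitted_learners_ : list[FittedLearner]  (full-training refits)
    """

    def __init__(
        self,
        base_specs: Sequence[LearnerSpec],
        method: str = "optimized",
        window_size: int = 8,
        ewa_error_metric: str = "rrmse",
    ):
        self.base_specs = base_specs
        self.method = method
        self.window_size = window_size
        self.ewa_error_metric = ewa_error_metric

    def fit(self, train: PanelDataset, plan: SplitPlan | None = None):
        if self.method not in ("optimized", "average", "ewa"):
            raise ValueError(f"unknown method {self.method!r}")
        if plan is None:
            plan = make_walk_forward_plan(train.years, self.window_size)
        self.plan_ = plan
        self.oob_ = generate_oob(self.base_specs, train, plan)
        if self.method == "optimized":
            self.weights_ = optimize_weights(self.oob_)
        elif self.method == "average":
            w = average_weights(self.oob_.k, self.oob_.learner_names)
            self.weights_ = EnsembleWeights(
                w.weights, w.learner_names, "average",
                oob_objective=_oob_objective(self.oob_, w.w),
            )
        else:
            self.weights_ = ewa_weights(self.oob_, self.ewa_error_metric)
        self.fitted_learners_ = [
            learners.fit(spec, train.X, train.y) for spec in self.base_specs
        ]
        self.feature_names_ = train.features
        return self

    def _base_prediction_matrix(self, X: pd.DataFrame) -> np.ndarray:
        return np.column_stack([m.predict(X) for m in self.fitted_learners_])

    def predict(self, X: pd.DataFrame | PanelDataset) -> np.ndarray:
        if isinstance(X, PanelDataset):
            X = X.X
        return predict_weighted(self.weights_, self._base_prediction_matrix(X))


class StackedEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Two-level stacked generalization on blocked OOB predictions.

    The second-level learner sees only the k OOB prediction columns as
    inputs.  Supported second-level families: linear, lasso, random_forest,
    gbm_lgbm.
    """

    def __init__(
        self,
        base_specs: Sequence[LearnerSpec],
        second_level: LearnerSpec | None = None,
        window_size: int = 8,
    ):
        self.base_specs = base_specs
        self.second_level = second_level
        self.window_size = window_size

    def fit(self, train: PanelDataset, plan: SplitPlan | None = None):
        second = self.second_level or LearnerSpec(name="stack_linear", family="linear")
        if second.family not in STACKING_FAMILIES:
            raise ValueError(
                f"unsupported second-level family {second.family!r}; "
                f"choose one of {STACKING_FAMILIES}"
            )
        if plan is None:
            plan = make_walk_forward_plan(train.years, self.window_size)
        self.plan_ = plan
        self.oob_ = generate_oob(self.base_specs, train, plan)
        Z = self.oob_.frame[self.oob_.learner_names]
        self.second_level_model_ = learners.fit(second, Z, self.oob_.y)
        self.fitted_learners_ = [
            learners.fit(spec, train.X, train.y) for spec in self.base_specs
        ]
        self.feature_names_ = train.features
        return self

    def predict(self, X: pd.DataFrame | PanelDataset) -> np.ndarray:
        if isinstance(X, PanelDataset):
            X = X.X
        Z = pd.DataFrame(
            {m.spec.name: m.predict(X) for m in self.fitted_learners_},
            columns=list(self.oob_.learner_names),
        )
        return self.second_level_model_.predict(Z)


def fit_stacked(
    oob: OOBMatrix,
    second_level: LearnerSpec,
    base_specs: Sequence[LearnerSpec] | None = None,
    train: PanelDataset | None = None,
) -> StackedEnsembleRegressor | FittedLearner:
    """Fit the second level on an existing OOB matrix.

    With ``base_specs``/``train`` given, returns a deployable
    :class:`StackedEnsembleRegressor`; otherwise returns just the fitted
    second-level learner (useful for OOB-space analysis).
    """
    if second_level.family not in STACKING_FAMILIES:
        raise ValueError(
            f"unsupported second-level family {second_level.family!r}; "
            f"choose one of {STACKING_FAMILIES}"
        )
    Z = oob.frame[oob.learner_names]
    second = learners.fit(second_level, Z, oob.y)
    if base_specs is None or train is None:
        return second
    model = StackedEnsembleRegressor(base_specs, second_level)
    model.plan_ = None
    model.oob_ = oob
    model.second_level_model_ = second
    model.fitted_learners_ = [learners.fit(s, train.X, train.y) for s in base_specs]
    model.feature_names_ = train.features
    return model


def predict_stacked(model: StackedEnsembleRegressor, X) -> np.ndarray:
    return model.predict(X)
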