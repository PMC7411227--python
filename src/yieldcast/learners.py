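"""Uniform base-learner contract.

Every model in the stack — ordinary least squares, LASSO, random forest,
XGBoost, LightGBM and the dummy training-mean baseline — is addressed through
the same two calls: ``fit(spec, X, y) -> FittedLearner`` and
``FittedLearner.predict(X)``.  The linear families implement the two losses

    OLS:    L = sum_i (y_i - yhat_i)^2
    LASSO:  L = sum_i (y_i - yhat_i)^2 + lambda * sum_j |beta_j|

with the intercept unpenalized; the tree families delegate to established
gradient-boosting / random-forest implementations, honoring the declared seed.
LASSO is solved by coordinate descent via scikit-learn, whose objective
(1/(2n))*RSS + alpha*||beta||_1 maps onto the loss above with
alpha = lambda / (2n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

FAMILIES = (
    "linear",
    "lasso",
    "random_forest",
    "gbm_xgb",
    "gbm_lgbm",
    "dummy_mean",
    "custom",
)


@dataclass(frozen=True)
class LearnerSpec:
    """Declarative description of one base learner.

    ``hyperparameters`` are family-specific; for ``lasso`` the key ``lam``
    holds the L1 shrinkage weight of the penalized least-squares loss.
    ``custom`` carries a ``factory`` hyperparameter returning an object with
    sklearn-style fit/predict (used for probes and test doubles).
    """

    name: str
    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if self.family == "lasso":
            lam = self.hyperparameters.get("lam", 1.0)
            if lam < 0:
                raise ValueError("lasso shrinkage lam must be >= 0")
        if self.family == "custom" and "factory" not in self.hyperparameters:
            raise ValueError("custom family requires a 'factory' hyperparameter")

    # frozen dataclass with a dict field: hash by identity-relevant parts
    def __hash__(self) -> int:  # pragma: no cover
        return hash((self.name, self.family, self.seed))


class _DummyMean:
    """Predicts the training-mean response everywhere."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


def _build_estimator(spec: LearnerSpec, n_rows: int, n_features: int):
    hp = dict(spec.hyperparameters)
    if spec.family == "linear":
        from sklearn.linear_model import LinearRegression

        return LinearRegression(**hp)
    if spec.family == "lasso":
        lam = hp.pop("lam", 1.0)
        if lam == 0:
            from sklearn.linear_model import LinearRegression

            return LinearRegression(**hp)
        from sklearn.linear_model import Lasso

        alpha = lam / (2.0 * n_rows)
        hp.setdefault("max_iter", 10_000)
        hp.setdefault("tol", 1e-7)
        return Lasso(alpha=alpha, **hp)
    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        hp.setdefault("n_estimators", 200)
        hp.setdefault("n_jobs", 1)
        return RandomForestRegressor(random_state=spec.seed, **hp)
    if spec.family == "gbm_xgb":
        from xgboost import XGBRegressor

        hp.setdefault("n_estimators", 200)
        hp.setdefault("n_jobs", 1)
        hp.setdefault("verbosity", 0)
        return XGBRegressor(random_state=spec.seed, **hp)
    if spec.family == "gbm_lgbm":
        from lightgbm import LGBMRegressor

        hp.setdefault("n_estimators", 200)
        hp.setdefault("n_jobs", 1)
        hp.setdefault("verbose", -1)
        return LGBMRegressor(random_state=spec.seed, **hp)
    if spec.family == "dummy_mean":
        return _DummyMean()
    if spec.family == "custom":
        return hp["factory"]()
    raise ValueError(spec.family)  # unreachable: validated in LearnerSpec


@dataclass
class FittedLearner:
    """A fitted base learner bound to its training feature list.

    Prediction requires exactly the training features, in the same order —
    a deliberate guard against silent column misalignment between folds.
    """

    spec: LearnerSpec
    estimator: Any
    feature_names: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            extra = [c for c in X.columns if c not in self.feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature mismatch for learner {self.spec.name!r}: "
                    f"missing={missing} extra={extra}"
                )
            X = X[self.feature_names]
        else:
            X = np.asarray(X)
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, got {X.shape[1]}"
                )
        Xf = pd.DataFrame(np.asarray(X, dtype=float), columns=self.feature_names)
        return np.asarray(self.estimator.predict(Xf)).astype(float)


def fit(spec: LearnerSpec, X: pd.DataFrame, y: Sequence[float]) -> FittedLearner:
    """Fit one learner on a feature table and response vector."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_names = [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float)
    if Xv.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit")
    if np.isnan(Xv).any() or np.isnan(yv).any():
        raise ValueError("missing values are not supported; impute upstream")
    if spec.family == "linear" and Xv.shape[1] >= Xv.shape[0]:
        raise ValueError(
            "singular design: more features than rows for the linear family; "
            "use the lasso or a tree family instead"
        )
    est = _build_estimator(spec, n_rows=Xv.shape[0], n_features=Xv.shape[1])
    est.fit(pd.DataFrame(Xv, columns=feature_names), yv)
    return FittedLearner(spec=spec, estimator=est, feature_names=feature_names)


def lasso_loss(X, y, coef: np.ndarray, intercept: float, lam: float) -> float:
    """The penalized least-squares loss: RSS + lam * ||beta||_1 (no intercept)."""
    Xv = np.asarray(X, dtype=float)
    resid = np.asarray(y, dtype=float) - (Xv @ coef + intercept)
    return float(resid @ resid + lam * np.abs(coef).sum())
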