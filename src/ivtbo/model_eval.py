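"""Leave-one-out comparison of surrogate families on an experiment log.

Each candidate surrogate is trained on every fold of size n-1 and scored by
the absolute prediction error on the held-out reaction; the error
distributions (GP vs random forest vs gradient boosting, by default) are the
comparison — no significance testing, just distributions.
"""

from __future__ import annotations

from typing import Callable, Mapping, Protocol

import numpy as np
import pandas as pd

from . import gp
from .optimizer import ExperimentLog

__all__ = [
    "loo_errors",
    "compare",
    "gp_factory",
    "rf_factory",
    "gbm_factory",
    "default_factories",
]


class Regressor(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Regressor": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


RegressorFactory = Callable[[int], Regressor]
"""Builds a fresh regressor from a seed; must not share state across folds."""


class _GPRegressor:
    def __init__(self, seed: int, restarts: int = 4):
        self.seed = seed
        self.restarts = restarts
        self.model: gp.GPModel | None = None

    def fit(self, X, y):
        self.model = gp.fit(X, y, restarts=self.restarts, seed=self.seed)
        return self

    def predict(self, X):
        mu, _ = gp.predict(self.model, np.atleast_2d(X))
        return mu


def gp_factory(seed: int) -> Regressor:
    """The in-repo GP surrogate under the fit/predict contract."""
    return _GPRegressor(seed)


def rf_factory(seed: int) -> Regressor:
    from sklearn.ensemble import RandomForestRegressor

    return RandomForestRegressor(n_estimators=200, random_state=seed)


def gbm_factory(seed: int) -> Regressor:
    from sklearn.ensemble import GradientBoostingRegressor

    return GradientBoostingRegressor(random_state=seed)


def default_factories() -> dict[str, RegressorFactory]:
    return {"gp": gp_factory, "rf": rf_factory, "gbm": gbm_factory}


def loo_errors(
    factory: RegressorFactory, log: ExperimentLog, seed: int = 0
) -> np.ndarray:
    """Absolute leave-one-out errors |y_i - yhat_{-i}(x_i)|, in log order.

    A fresh regressor is built per fold; the held-out target never enters
    training.  Deterministic given the factory seed.
    """
    n = len(log)
    if n < 3:
        raise ValueError("need at least 3 observations for leave-one-out")
    X = log.encoded()
    y = log.yields
    errs = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        try:
            reg = factory(seed)
            reg.fit(X[mask], y[mask])
            pred = np.asarray(reg.predict(X[i : i + 1])).ravel()[0]
        except Exception as e:
            raise RuntimeError(f"regressor failed on fold {i}") from e
        errs[i] = abs(y[i] - pred)
    return errs


def compare(
    factories: Mapping[str, RegressorFactory],
    log: ExperimentLog,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LOO error distributions per model, plus a median/IQR summary table.

    Returns ``(errors, summary)``: errors has one column per model (paired
    per-point values, box-plot ready); summary has median and IQR rows.
    """
    if not factories:
        raise ValueError("need at least one factory")
    errors = pd.DataFrame(
        {name: loo_errors(f, log, seed=seed) for name, f in factories.items()}
    )
    q1, med, q3 = (errors.quantile(q) for q in (0.25, 0.5, 0.75))
    summary = pd.DataFrame(
        {"median": med, "q1": q1, "q3": q3, "iqr": q3 - q1}
    )
    return errors, summary
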