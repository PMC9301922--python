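"""Out-of-sample and out-of-city cross-validation and accuracy metrics.

Random-record 10-fold CV measures how well the estimator fits the
station network it was trained on; grouped ("out-of-city") 10-fold CV
holds out entire cities and therefore measures spatial predictive skill
at locations with no monitors — the harder task, since no neighbouring
station leaks information into the training set.

The reported R² is the squared Pearson correlation between held-out
predictions and observations (the convention of the satellite
air-quality literature); the Nash–Sutcliffe form 1 − SSE/SST is reported
alongside.  The regression slope/intercept are OLS of predicted on
observed, so a slope below 1 reads as a low bias of the predictions.
Held-out predictions are pooled over folds before metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cascade import CascadeConfig

__all__ = [
    "FoldPlan",
    "Metrics",
    "make_folds",
    "evaluate",
    "cross_validate",
    "CrossValidationResult",
]


@dataclass
class FoldPlan:
    k: int
    fold_index: np.ndarray  # per-record fold id in [0, k)
    scheme: str  # "random" | "grouped"
    seed: int


@dataclass
class Metrics:
    n: int
    cv_r2: float
    nse_r2: float
    rmse: float
    mae: float
    slope: float
    intercept: float
    zero_variance: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def make_folds(
    n_records: int,
    k: int,
    scheme: str = "random",
    seed: int = 0,
    cities: Sequence | None = None,
) -> FoldPlan:
    """Partition records into k folds.

    ``scheme="random"`` shuffles record indices into near-equal folds;
    ``scheme="grouped"`` shuffles the distinct city labels and assigns
    them round-robin, so no city is ever split across folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold = np.empty(n_records, dtype=int)
    if scheme == "random":
        perm = rng.permutation(n_records)
        for fi, chunk in enumerate(np.array_split(perm, k)):
            fold[chunk] = fi
    elif scheme == "grouped":
        if cities is None:
            raise ValueError("grouped scheme requires city labels")
        cities = np.asarray(cities)
        if len(cities) != n_records:
            raise ValueError("city labels must align with records")
        unique = np.unique(cities)
        if len(unique) < k:
            raise ValueError(f"grouped scheme needs >= {k} distinct cities, got {len(unique)}")
        order = rng.permutation(len(unique))
        city_fold = {unique[ci]: fi % k for fi, ci in enumerate(order)}
        fold = np.array([city_fold[c] for c in cities])
    else:
        raise ValueError("scheme must be 'random' or 'grouped'")
    return FoldPlan(k=k, fold_index=fold, scheme=scheme, seed=seed)


def evaluate(observed, predicted) -> Metrics:
    """Accuracy metrics of predictions against observations.

    RMSE = sqrt(mean (p−o)²); MAE = mean |p−o|; CV-R² = corr(o,p)²;
    NSE-R² = 1 − SSE/SST; slope/intercept from OLS of p on o.  A
    zero-variance observed vector flags the correlation-based metrics as
    undefined (NaN) instead of raising.
    """
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if len(o) != len(p) or len(o) < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    err = p - o
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        return Metrics(len(o), np.nan, np.nan, rmse, mae, np.nan, np.nan, zero_variance=True)
    nse = float(1.0 - np.sum(err**2) / sst)
    lr = stats.linregress(o, p)
    cv_r2 = float(lr.rvalue**2) if np.isfinite(lr.rvalue) else np.nan
    return Metrics(len(o), cv_r2, nse, rmse, mae, float(lr.slope), float(lr.intercept))


@dataclass
class CrossValidationResult:
    pooled: Metrics
    per_fold: list[Metrics]
    predictions: pd.DataFrame  # record-aligned: observed, predicted, fold (+ meta)

    def per_group(self, column: str) -> pd.DataFrame:
        """Metric breakdown by a metadata column (e.g. station or date)."""
        rows = []
        for key, g in self.predictions.groupby(column):
            if len(g) >= 2:
                m = evaluate(g["observed"], g["predicted"]).as_dict()
                m[column] = key
                rows.append(m)
        return pd.DataFrame(rows)


def cross_validate(
    X: pd.DataFrame,
    y,
    plan: FoldPlan,
    config: CascadeConfig | None = None,
    meta: pd.DataFrame | None = None,
    estimator_factory: Callable | None = None,
) -> CrossValidationResult:
    """k-fold cross-validation of the cascade under a fold plan.

    For each fold the estimator is trained on the remaining k−1 folds and
    predicts the held-out fold; pooled metrics are computed on the
    concatenated held-out predictions.  ``estimator_factory(fold)`` may
    override the default cascade construction.  A fold whose training
    partition is too small for the estimator is skipped with a warning.
    """
    config = config or CascadeConfig()
    y = np.asarray(y, dtype=float).ravel()
    if len(plan.fold_index) != len(y):
        raise ValueError("fold plan does not cover the records")
    observed = np.full(len(y), np.nan)
    predicted = np.full(len(y), np.nan)
    per_fold: list[Metrics] = []
    for fi in range(plan.k):
        te = plan.fold_index == fi
        tr = ~te
        if not te.any():
            continue
        # one seed for every fold: pooled metrics then depend only on the
        # partition, not on fold labels or processing order
        est = estimator_factory(fi) if estimator_factory else config.estimator()
        try:
            est.fit(X.loc[tr] if isinstance(X, pd.DataFrame) else X[tr], y[tr])
        except ValueError as exc:
            warnings.warn(f"fold {fi} skipped: {exc}")
            continue
        pred = est.predict(X.loc[te] if isinstance(X, pd.DataFrame) else X[te])
        observed[te] = y[te]
        predicted[te] = pred
        per_fold.append(evaluate(y[te], pred))
    done = np.isfinite(predicted)
    pooled = evaluate(observed[done], predicted[done])
    out = pd.DataFrame(
        {"observed": observed[done], "predicted": predicted[done], "fold": plan.fold_index[done]}
    )
    if meta is not None:
        out = pd.concat([meta.loc[done].reset_index(drop=True), out.reset_index(drop=True)], axis=1)
    return CrossValidationResult(pooled=pooled, per_fold=per_fold, predictions=out)
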