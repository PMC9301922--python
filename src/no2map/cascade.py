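"""Cascade ("deep") forest regression for surface-NO₂ estimation.

A cascade forest stacks layers of forests the way a deep network stacks
layers of neurons: layer l is trained on the original feature table
augmented with the predictions of layer l−1's forests.  During training
the augmented features are out-of-fold predictions (k-fold within the
training set, so no forest ever predicts its own training rows — the
standard guard against label leakage between layers); at predict time
the retained full forests provide the augmentation.  Layers are added
while the layer's k-fold validation RMSE improves and the cascade is
truncated at the best layer, so the retained depth adapts to the data
without hyper-parameter search.

Each layer holds random forests and extremely randomized (completely
random split) forests; the two split rules give the next layer decorrelated
views of the data.  The final prediction is the mean over the last
layer's forests, which by construction lies inside the training target
range.

Determinism: the forest in slot f of layer l is seeded from
``SeedSequence((random_state, l, f))`` and the layer's fold split from
``SeedSequence((random_state, l, 10_000))``, so identical inputs and
seed give bit-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CascadeForestRegressor",
    "CascadeConfig",
    "train_cascade",
    "predict_cascade",
    "feature_importance",
]


def _forest_seed(random_state: int, layer: int, slot: int) -> int:
    return int(np.random.SeedSequence((random_state, layer, slot)).generate_state(1)[0] % (2**31))


def _fold_seed(random_state: int, layer: int) -> int:
    return int(
        np.random.SeedSequence((random_state, layer, 10_000)).generate_state(1)[0] % (2**31)
    )


@dataclass
class _Layer:
    forests: list
    oof: np.ndarray  # training-time augmentation, shape (n, n_forests)
    rmse: float


class CascadeForestRegressor(RegressorMixin, BaseEstimator):
    """Adaptive-depth cascade of random and extremely randomized forests.

    Parameters
    ----------
    n_random_forests, n_extra_trees : forests per layer of each kind
        (random forests first, then extra-trees, in slot order).
    n_estimators : trees per forest.
    k_folds : folds for the out-of-fold augmentation and the layer
        validation metric.
    max_layers : depth cap.
    patience : layers without improvement tolerated before stopping.
    min_samples_leaf, max_features : forwarded to every forest;
        ``"sqrt"`` feature sampling follows common cascade-forest
        practice and keeps single-CPU training tractable.
    random_state : master seed (see module docstring for the derivation).

    Attributes
    ----------
    n_layers_ : retained depth.
    layer_rmse_ : k-fold validation RMSE per retained layer
        (non-increasing by the growth rule).
    feature_importances_ : impurity importances over the *original*
        features, aggregated across every forest of every retained layer;
        an augmented feature's importance is redistributed onto its
        source forest's own original-feature importances.  Non-negative,
        sums to 1.
    """

    def __init__(
        self,
        n_random_forests: int = 2,
        n_extra_trees: int = 2,
        n_estimators: int = 100,
        k_folds: int = 3,
        max_layers: int = 10,
        patience: int = 1,
        min_samples_leaf: int = 5,
        max_features: str | float = "sqrt",
        random_state: int = 0,
        n_jobs: int = 1,
    ) -> None:
        self.n_random_forests = n_random_forests
        self.n_extra_trees = n_extra_trees
        self.n_estimators = n_estimators
        self.k_folds = k_folds
        self.max_layers = max_layers
        self.patience = patience
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.random_state = random_state
        self.n_jobs = n_jobs

    # ------------------------------------------------------------------
    def _forest_protos(self) -> list:
        common = dict(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            n_jobs=self.n_jobs,
        )
        protos = [RandomForestRegressor(**common) for _ in range(self.n_random_forests)]
        protos += [ExtraTreesRegressor(**common) for _ in range(self.n_extra_trees)]
        return protos

    @staticmethod
    def _as_array(X) -> tuple[np.ndarray, list[str] | None]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        return np.asarray(X, dtype=float), None

    def fit(self, X, y) -> "CascadeForestRegressor":
        Xa, names = self._as_array(X)
        y = np.asarray(y, dtype=float).ravel()
        if Xa.ndim != 2 or len(Xa) != len(y):
            raise ValueError("X must be 2-D with one row per target value")
        if not np.all(np.isfinite(Xa)):
            raise ValueError("X contains non-finite values")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        n_forests = self.n_random_forests + self.n_extra_trees
        if n_forests < 1 or self.k_folds < 2 or self.max_layers < 1:
            raise ValueError("invalid cascade configuration")
        if len(y) < self.k_folds * n_forests:
            raise ValueError("too few samples for the configured folds and forests")

        self.feature_names_in_ = names
        self.n_features_in_ = Xa.shape[1]
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())

        layers: list[_Layer] = []
        best_rmse, best_depth, since_best = np.inf, 0, 0
        aug = np.empty((len(y), 0))
        for li in range(self.max_layers):
            Xl = np.hstack([Xa, aug])
            forests, oof = [], np.empty((len(y), n_forests))
            kf = KFold(self.k_folds, shuffle=True, random_state=_fold_seed(self.random_state, li))
            splits = list(kf.split(Xl))
            for fi, proto in enumerate(self._forest_protos()):
                fseed = _forest_seed(self.random_state, li, fi)
                full = clone(proto).set_params(random_state=fseed)
                full.fit(Xl, y)
                forests.append(full)
                for si, (tr, te) in enumerate(splits):
                    sub = clone(proto).set_params(
                        random_state=_forest_seed(self.random_state, li, fi * 1000 + si + 1)
                    )
                    sub.fit(Xl[tr], y[tr])
                    oof[te, fi] = sub.predict(Xl[te])
            rmse = float(np.sqrt(np.mean((oof.mean(axis=1) - y) ** 2)))
            layers.append(_Layer(forests, oof, rmse))
            if rmse < best_rmse:
                best_rmse, best_depth, since_best = rmse, li + 1, 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
            aug = oof
        self.layers_ = layers[:best_depth]
        self.n_layers_ = best_depth
        self.layer_rmse_ = [l.rmse for l in self.layers_]
        self.feature_importances_ = self._resolve_importances()
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "layers_")
        Xa, names = self._as_array(X)
        if names is not None and self.feature_names_in_ is not None:
            if names != self.feature_names_in_:
                raise ValueError("feature names do not match those seen at fit time")
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError("feature count does not match fit time")
        aug = np.empty((len(Xa), 0))
        for layer in self.layers_:
            Xl = np.hstack([Xa, aug])
            aug = np.column_stack([f.predict(Xl) for f in layer.forests])
        return aug.mean(axis=1)

    # ------------------------------------------------------------------
    def _resolve_importances(self) -> np.ndarray:
        d = self.n_features_in_
        resolved_prev: list[np.ndarray] = []
        total = np.zeros(d)
        for layer in self.layers_:
            resolved_here = []
            for f in layer.forests:
                imp = f.feature_importances_
                vec = imp[:d].copy()
                for j, src in enumerate(resolved_prev):
                    vec += imp[d + j] * src
                s = vec.sum()
                resolved_here.append(vec / s if s > 0 else np.full(d, 1.0 / d))
                total += resolved_here[-1]
            resolved_prev = resolved_here
        return total / total.sum()

    def named_importances(self) -> pd.Series:
        check_is_fitted(self, "feature_importances_")
        names = self.feature_names_in_ or [f"x{i}" for i in range(self.n_features_in_)]
        return pd.Series(self.feature_importances_, index=names).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Thin functional interface + per-year training
# ---------------------------------------------------------------------------


@dataclass
class CascadeConfig:
    """Bag of cascade hyper-parameters (maps 1:1 onto the estimator)."""

    n_random_forests: int = 2
    n_extra_trees: int = 2
    n_estimators: int = 100
    k_folds: int = 3
    max_layers: int = 10
    patience: int = 1
    min_samples_leaf: int = 5
    max_features: str | float = "sqrt"
    per_year: bool = True
    random_state: int = 0
    n_jobs: int = 1

    def estimator(self, seed_offset: int = 0) -> CascadeForestRegressor:
        kw = {k: v for k, v in self.__dict__.items() if k != "per_year"}
        kw["random_state"] = self.random_state + seed_offset
        return CascadeForestRegressor(**kw)


def train_cascade(
    X,
    y,
    config: CascadeConfig | None = None,
    dates=None,
):
    """Train the surface estimator; one model per calendar year if asked.

    With ``config.per_year`` (the default) and a ``dates`` vector
    spanning several years, an independent cascade is fitted per year and
    returned as ``{year: model}``; otherwise a single fitted
    :class:`CascadeForestRegressor`.
    """
    config = config or CascadeConfig()
    if config.per_year and dates is not None:
        years = pd.DatetimeIndex(dates).year
        unique = np.unique(years)
        if len(unique) > 1:
            models = {}
            for yr in unique:
                m = config.estimator(seed_offset=int(yr))
                sel = years == yr
                models[int(yr)] = m.fit(
                    X.loc[sel] if isinstance(X, pd.DataFrame) else X[sel],
                    np.asarray(y)[sel],
                )
            return models
    return config.estimator().fit(X, y)


def predict_cascade(model, X, dates=None) -> np.ndarray:
    """Predict surface NO₂ (μg/m³) from a trained cascade (or per-year dict)."""
    if isinstance(model, dict):
        if dates is None:
            raise ValueError("per-year model needs the sample dates")
        years = pd.DatetimeIndex(dates).year
        out = np.empty(len(X))
        for yr, m in model.items():
            sel = years == yr
            if sel.any():
                out[sel] = m.predict(X.loc[sel] if isinstance(X, pd.DataFrame) else X[sel])
        return out
    return model.predict(X)


def feature_importance(model) -> pd.Series:
    """Normalised original-feature importances of a trained cascade."""
    if isinstance(model, dict):
        parts = [m.named_importances() for m in model.values()]
        s = sum(parts) / len(parts)
        return s.sort_values(ascending=False)
    return model.named_importances()
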