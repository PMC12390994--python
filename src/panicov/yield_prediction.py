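"""Predict yield components from the five coverage-curve parameters.

Workflow: a Pearson correlation screen of the dynamic parameters
(K, g, d0, a, d1) against the six yield components (Yield, GN, PN, GNP,
TGW, FGR); four regression configurations — partial least squares
(3 components), random forest (100 trees), gradient boosting and extreme
gradient boosting (100 stages, learning rate 0.05) — evaluated by
leave-one-out cross-validation; RMSE and R^2 on the pooled out-of-fold
predictions; and exact Shapley feature attribution for the tree
ensembles.

RMSE is sqrt(mean squared error) and R^2 is 1 - SSres/SStot against the
observed mean; R^2 may be negative and is not clipped. Both are computed
once on the pooled LOOCV predictions — the only convention that is
well-defined when every fold holds a single observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

FEATURES = ("K", "g", "d0", "a", "d1")
TARGETS = ("Yield", "GN", "PN", "GNP", "TGW", "FGR")
MODEL_NAMES = ("plsr", "rfr", "gbr", "xgbr")

__all__ = [
    "FEATURES",
    "TARGETS",
    "MODEL_NAMES",
    "CVResult",
    "AttributionReport",
    "UnsupportedModelError",
    "correlation_screen",
    "rmse",
    "r_squared",
    "make_model",
    "loocv",
    "attribute",
    "linear_attribution",
    "report_table",
]


@dataclass
class CVResult:
    model_name: str
    target_name: str
    r_squared: float
    rmse: float
    actual: np.ndarray
    predicted: np.ndarray


@dataclass
class AttributionReport:
    """Per-record additive feature contributions, in target units.

    base_value + sum(contributions[i]) equals the model prediction for
    record i (the additivity/efficiency property of Shapley values).
    """

    feature_names: tuple[str, ...]
    contributions: np.ndarray  # n_records x n_features
    base_value: float
    predictions: np.ndarray

    def ranking(self) -> pd.Series:
        """Features ranked by mean absolute contribution, descending."""
        imp = np.abs(self.contributions).mean(axis=0)
        return pd.Series(imp, index=list(self.feature_names)).sort_values(
            ascending=False
        )


class UnsupportedModelError(TypeError):
    """Shapley attribution here covers tree ensembles only."""


def correlation_screen(
    records: pd.DataFrame,
    features=FEATURES,
    targets=TARGETS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every feature x target pair.

    Returns (r, p, stars) DataFrames indexed by feature with target
    columns. Stars follow the usual convention: * p<0.05, ** p<0.01,
    *** p<0.001, 'ns' otherwise. Zero-variance columns yield NaN r and a
    '!' flag instead of a star.
    """
    for col in (*features, *targets):
        if col not in records.columns:
            raise KeyError(f"column {col!r} missing from records")
    if len(records) < 3:
        raise ValueError("need at least 3 records for a correlation screen")
    r = pd.DataFrame(index=list(features), columns=list(targets), dtype=float)
    p = r.copy()
    stars = pd.DataFrame("", index=list(features), columns=list(targets))
    for f in features:
        for t in targets:
            x = records[f].to_numpy(dtype=float)
            y = records[t].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r.loc[f, t] = np.nan
                p.loc[f, t] = np.nan
                stars.loc[f, t] = "!"
                continue
            res = stats.pearsonr(x, y)
            r.loc[f, t] = res.statistic
            p.loc[f, t] = res.pvalue
            pv = res.pvalue
            stars.loc[f, t] = (
                "***" if pv < 0.001 else "**" if pv < 0.01 else "*" if pv < 0.05 else "ns"
            )
    return r, p, stars


def rmse(actual, predicted, literal_half: bool = False) -> float:
    """Root mean squared error.

    ``literal_half=True`` divides the sum of squares by 2 instead of n —
    a compatibility form some reports print; the mean convention is the
    default and the one used everywhere in this package.
    """
    a = np.asarray(actual, dtype=float)
    pr = np.asarray(predicted, dtype=float)
    if a.shape != pr.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length and non-empty")
    ss = float(np.sum((pr - a) ** 2))
    return float(np.sqrt(ss / (2.0 if literal_half else a.size)))


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 - SSres/SStot; may be negative."""
    a = np.asarray(actual, dtype=float)
    pr = np.asarray(predicted, dtype=float)
    if a.shape != pr.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length and non-empty")
    sstot = float(np.sum((a - a.mean()) ** 2))
    if sstot == 0:
        raise ValueError("actual values have zero variance; R^2 undefined")
    ssres = float(np.sum((a - pr) ** 2))
    return 1.0 - ssres / sstot


def make_model(name: str, seed: int = 0):
    """Instantiate one of the four named regression configurations."""
    name = name.lower()
    if name == "plsr":
        return make_pipeline(StandardScaler(), PLSRegression(n_components=3))
    if name == "rfr":
        return RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "gbr":
        return GradientBoostingRegressor(
            n_estimators=100, learning_rate=0.05, random_state=seed
        )
    if name == "xgbr":
        return XGBRegressor(
            n_estimators=100,
            learning_rate=0.05,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def loocv(
    records: pd.DataFrame,
    model_name: str,
    target_name: str,
    seed: int = 0,
    features=FEATURES,
) -> CVResult:
    """Leave-one-out cross-validation of one model on one target.

    n folds; fold i trains on all records but i and predicts record i.
    Scores are computed once on the pooled predictions. Tree-ensemble
    randomness is fixed by ``seed``; feature standardization happens
    inside each training fold (via the PLSR pipeline) so no information
    leaks from the held-out record.
    """
    X = records.loc[:, list(features)].to_numpy(dtype=float)
    y = records.loc[:, target_name].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 records")
    preds = np.empty(n)
    for i in range(n):
        idx = np.arange(n) != i
        model = make_model(model_name, seed=seed)
        model.fit(X[idx], y[idx])
        preds[i] = np.ravel(model.predict(X[i : i + 1]))[0]
    return CVResult(
        model_name=model_name,
        target_name=target_name,
        r_squared=r_squared(y, preds),
        rmse=rmse(y, preds),
        actual=y,
        predicted=preds,
    )


_TREE_TYPES = (RandomForestRegressor, GradientBoostingRegressor, XGBRegressor)


def _subset_values(model, X: np.ndarray, background: np.ndarray) -> dict:
    """v(S) = E_bg[f(x_S, B_~S)] for every feature subset S, per record."""
    n, d = X.shape
    m = background.shape[0]
    values: dict[frozenset, np.ndarray] = {}
    for size in range(d + 1):
        for S in combinations(range(d), size):
            S = frozenset(S)
            # m background rows per record, with S columns overridden by x
            tiled = np.repeat(background[None, :, :], n, axis=0)  # n x m x d
            for j in S:
                tiled[:, :, j] = X[:, j : j + 1]
            preds = np.asarray(model.predict(tiled.reshape(n * m, d))).reshape(n, m)
            values[S] = preds.mean(axis=1)
    return values


def attribute(
    model, records: pd.DataFrame, background: pd.DataFrame | None = None,
    features=FEATURES,
) -> AttributionReport:
    """Exact Shapley attribution of a fitted tree ensemble's predictions.

    Computes interventional Shapley values by exhaustive enumeration of
    all 2^d feature coalitions (d = 5 here, 32 coalitions), marginalizing
    absent features over a background sample — exact, so additivity
    base + sum(contributions) = prediction holds to numerical precision.

    ``background`` defaults to the records themselves. Non-tree models are
    rejected; use :func:`linear_attribution` for the PLSR configuration.
    """
    if not isinstance(model, _TREE_TYPES):
        raise UnsupportedModelError(
            f"Shapley attribution supports tree ensembles {_TREE_TYPES}; "
            f"got {type(model).__name__}. For PLSR use linear_attribution."
        )
    X = records.loc[:, list(features)].to_numpy(dtype=float)
    bg = (background if background is not None else records).loc[
        :, list(features)
    ].to_numpy(dtype=float)
    n, d = X.shape
    v = _subset_values(model, X, bg)
    phi = np.zeros((n, d))
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for size in range(d):
            w = factorial(size) * factorial(d - size - 1) / factorial(d)
            for S in combinations(others, size):
                S = frozenset(S)
                phi[:, j] += w * (v[S | {j}] - v[S])
    base = float(v[frozenset()].mean())  # E_bg[f]; constant across records
    preds = np.asarray(model.predict(X)).astype(float)
    return AttributionReport(
        feature_names=tuple(features),
        contributions=phi,
        base_value=base,
        predictions=preds,
    )


def linear_attribution(
    pls_pipeline, records: pd.DataFrame, features=FEATURES
) -> AttributionReport:
    """Coefficient-based additive attribution for the PLSR pipeline.

    For a linear model f(x) = b + w.x the natural additive decomposition
    is phi_ij = w_j (x_ij - mean_j), which sums to f(x) - f(mean).
    """
    X = records.loc[:, list(features)].to_numpy(dtype=float)
    preds = np.ravel(pls_pipeline.predict(X))
    mu = X.mean(axis=0)
    base = float(np.ravel(pls_pipeline.predict(mu[None, :]))[0])
    scaler = pls_pipeline.named_steps["standardscaler"]
    pls = pls_pipeline.named_steps["plsregression"]
    w = np.ravel(pls.coef_) / scaler.scale_
    phi = (X - mu) * w
    return AttributionReport(
        feature_names=tuple(features),
        contributions=phi,
        base_value=base,
        predictions=preds,
    )


def report_table(cv_results: list[CVResult]) -> pd.DataFrame:
    """Wide performance table: rows = (target, metric), columns = models."""
    if not cv_results:
        raise ValueError("no CV results to tabulate")
    models = [m for m in MODEL_NAMES if any(r.model_name == m for r in cv_results)]
    targets = [t for t in TARGETS if any(r.target_name == t for r in cv_results)]
    index = pd.MultiIndex.from_product(
        [targets, ["R2", "RMSE"]], names=["target", "metric"]
    )
    table = pd.DataFrame(index=index, columns=models, dtype=float)
    for r in cv_results:
        table.loc[(r.target_name, "R2"), r.model_name] = r.r_squared
        table.loc[(r.target_name, "RMSE"), r.model_name] = r.rmse
    return table
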