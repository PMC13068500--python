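"""Boosted-regression-tree driver analysis.

Forward-stagewise gradient boosting (squared-error loss, bagged subsampling)
with the optimal tree count chosen at the 10-fold cross-validated deviance
minimum, a meta-parameter grid search (tree complexity × learning rate ×
bag fraction), permutation-based conditional importance normalized to
percentages, partial dependence, pairwise interaction strengths, and a
Moran's-I residual check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations, product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from mossar.trends import MoranResult, morans_i

__all__ = [
    "BRTConfig",
    "BRTModel",
    "default_grid",
    "reduced_grid",
    "tune_brt",
    "fit_at_config",
    "performance",
    "conditional_importance",
    "partial_dependence",
    "interaction_strength",
    "residual_spatial_check",
]


@dataclass(frozen=True)
class BRTConfig:
    """One meta-parameter combination for the boosting grid."""

    tree_complexity: int
    learning_rate: float
    bag_fraction: float
    cv_folds: int = 10
    step_size: int = 50
    max_trees: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")


#: default meta-parameter grid: 5 x 8 x 9 = 360 combinations
GRID_TREE_COMPLEXITY = (1, 2, 3, 4, 5)
GRID_LEARNING_RATE = (0.0005, 0.001, 0.0025, 0.005, 0.0075, 0.01, 0.025, 0.05)
GRID_BAG_FRACTION = (0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9)


def default_grid(**overrides) -> list[BRTConfig]:
    """The full 360-point grid of meta-parameter combinations."""
    return [
        BRTConfig(tc, lr, bf, **overrides)
        for tc, lr, bf in product(GRID_TREE_COMPLEXITY, GRID_LEARNING_RATE, GRID_BAG_FRACTION)
    ]


def reduced_grid(**overrides) -> list[BRTConfig]:
    """A 12-point grid for tests and quick runs (2 x 3 x 2)."""
    return [
        BRTConfig(tc, lr, bf, **overrides)
        for tc, lr, bf in product((1, 3), (0.005, 0.01, 0.05), (0.5, 0.75))
    ]


@dataclass
class BRTModel:
    """A tuned, refit boosting model plus its selection diagnostics."""

    config: BRTConfig
    n_trees_opt: int
    cv_deviance: float
    cv_correlation: float
    pseudo_r2: float
    estimator: GradientBoostingRegressor = field(repr=False)
    feature_names: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predictions always at the optimal tree count."""
        return self.estimator.predict(X[self.feature_names].to_numpy(float))


def _make_folds(n: int, cv_folds: int, stratify_by: np.ndarray, seed: int) -> np.ndarray:
    """Fold labels stratified by the rank of ``stratify_by``.

    Sorted indices are dealt round-robin into folds (with a seeded shuffle
    of the deal order) so each fold spans the full gradient; stabilizes CV
    on small samples.
    """
    rng = np.random.default_rng(seed)
    order = np.argsort(stratify_by, kind="stable")
    labels = np.empty(n, dtype=int)
    deal = np.tile(np.arange(cv_folds), n // cv_folds + 1)[:n]
    for start in range(0, n, cv_folds):
        block = deal[start:start + cv_folds].copy()
        rng.shuffle(block)
        deal[start:start + cv_folds] = block
    labels[order] = deal
    return labels


def _estimator(config: BRTConfig, n_trees: int, seed: int) -> GradientBoostingRegressor:
    return GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=n_trees,
        learning_rate=config.learning_rate,
        max_depth=config.tree_complexity,
        subsample=config.bag_fraction,
        random_state=seed,
    )


def _cv_curve(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    config: BRTConfig,
    folds: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted CV deviance per tree count, plus CV predictions per count.

    Returns (deviance_curve[max_trees], cv_pred[max_trees, n]).
    """
    n = len(y)
    cv_pred = np.zeros((config.max_trees, n))
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        est = _estimator(config, config.max_trees, seed)
        est.fit(X[train], y[train], sample_weight=w[train])
        for t, pred in enumerate(est.staged_predict(X[test])):
            cv_pred[t, test] = pred
    sq = (y[None, :] - cv_pred) ** 2
    deviance = (sq * w[None, :]).sum(axis=1) / w.sum()
    return deviance, cv_pred


def fit_at_config(
    X: pd.DataFrame,
    y,
    config: BRTConfig,
    weights=None,
    stratify_by=None,
    seed: int = 0,
) -> BRTModel:
    """CV tree-count selection and a full-data refit at one grid point."""
    y = np.asarray(y, float)
    n = len(y)
    if n < config.cv_folds:
        raise ValueError(f"need n >= cv_folds ({config.cv_folds}), got {n}")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to fit")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        w = w / w.mean()  # normalized to mean 1 in the loss
    strat = y if stratify_by is None else np.asarray(stratify_by, float)
    xmat = X.to_numpy(float)
    folds = _make_folds(n, config.cv_folds, strat, seed)
    deviance, cv_pred = _cv_curve(xmat, y, w, config, folds, seed)
    # candidate tree counts climb in steps; optimum at the deviance minimum
    candidates = np.arange(config.step_size - 1, config.max_trees, config.step_size)
    if candidates[-1] != config.max_trees - 1:
        candidates = np.append(candidates, config.max_trees - 1)
    best_idx = int(candidates[np.argmin(deviance[candidates])])
    n_opt = best_idx + 1
    pred_opt = cv_pred[best_idx]
    cv_corr = float(np.corrcoef(y, pred_opt)[0, 1]) if np.ptp(pred_opt) > 0 else 0.0

    final = _estimator(config, n_opt, seed)
    final.fit(xmat, y, sample_weight=w)
    train_pred = final.predict(xmat)
    dev_model = float(np.sum(w * (y - train_pred) ** 2))
    dev_null = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    pseudo_r2 = 1.0 - dev_model / dev_null
    return BRTModel(
        config=config,
        n_trees_opt=n_opt,
        cv_deviance=float(deviance[best_idx]),
        cv_correlation=cv_corr,
        pseudo_r2=pseudo_r2,
        estimator=final,
        feature_names=list(X.columns),
    )


def tune_brt(
    X: pd.DataFrame,
    y,
    weights=None,
    grid: Sequence[BRTConfig] | None = None,
    stratify_by=None,
    seed: int = 0,
) -> BRTModel:
    """Grid search over meta-parameters; the lowest CV deviance wins."""
    grid = list(default_grid() if grid is None else grid)
    if not grid:
        raise ValueError("empty meta-parameter grid")
    best: BRTModel | None = None
    for config in grid:
        model = fit_at_config(X, y, config, weights=weights, stratify_by=stratify_by, seed=seed)
        if best is None or model.cv_deviance < best.cv_deviance:
            best = model
    assert best is not None
    return best


def performance(model: BRTModel, X: pd.DataFrame, y) -> dict[str, float]:
    """RMSE, MAE and R² of observed vs predicted values."""
    y = np.asarray(y, float)
    pred = model.predict(X)
    err = y - pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else 1.0
    return {"rmse": rmse, "mae": mae, "r2": r2}


def conditional_importance(
    model: BRTModel, X: pd.DataFrame, y, n_perm: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Permutation-based conditional importance, normalized to sum to 100.

    For each predictor the column is independently permuted ``n_perm``
    times (others fixed) and the mean RMSE increase over the unpermuted
    baseline recorded; negative means are floored at zero before
    normalizing to percentages.
    """
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    base_rmse = performance(model, X, y)["rmse"]
    raw = {}
    for col in model.feature_names:
        increases = np.empty(n_perm)
        xp = X.copy()
        for b in range(n_perm):
            xp[col] = rng.permutation(X[col].to_numpy())
            err = y - model.predict(xp)
            increases[b] = np.sqrt(np.mean(err**2)) - base_rmse
        raw[col] = float(increases.mean())
    floored = {c: max(v, 0.0) for c, v in raw.items()}
    total = sum(floored.values())
    if total > 0:
        ri = {c: 100.0 * v / total for c, v in floored.items()}
    else:  # degenerate model with no usable splits: spread evenly
        ri = {c: 100.0 / len(floored) for c in floored}
    out = pd.DataFrame(
        {"ri": pd.Series(ri), "raw_rmse_increase": pd.Series(raw)}
    ).rename_axis("predictor")
    return out.sort_values("ri", ascending=False)


def partial_dependence(
    model: BRTModel, X: pd.DataFrame, predictor: str, n_grid: int = 50
) -> pd.DataFrame:
    """Centered partial-dependence curve for one predictor.

    Average prediction over the data with the focal column replaced by each
    grid value; the curve is centered by subtracting its own mean.
    """
    col = X[predictor].to_numpy(float)
    grid = np.linspace(col.min(), col.max(), n_grid)
    xp = X.copy()
    effects = np.empty(n_grid)
    for i, value in enumerate(grid):
        xp[predictor] = value
        effects[i] = model.predict(xp).mean()
    effects -= effects.mean()
    return pd.DataFrame({"value": grid, "effect": effects})


def _pd_at_points(model: BRTModel, X: pd.DataFrame, cols: tuple[str, ...]) -> np.ndarray:
    """Partial dependence of ``cols`` evaluated at the observed data points."""
    n = len(X)
    out = np.empty(n)
    xp = X.copy()
    for i in range(n):
        for c in cols:
            xp[c] = X[c].iloc[i]
        out[i] = model.predict(xp).mean()
    return out - out.mean()


def interaction_strength(model: BRTModel, X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise interaction strengths (Friedman-H style), symmetric matrix.

    For each pair, the centered two-variable partial-dependence surface is
    compared with the sum of the centered one-variable effects at the data
    points; the strength is the standard deviation of the residual surface.
    Depth-1 trees cannot interact, so tree_complexity == 1 yields an empty
    result with a warning.
    """
    names = model.feature_names
    if model.config.tree_complexity <= 1:
        warnings.warn("tree_complexity = 1: no pairwise interactions possible", stacklevel=2)
        return pd.DataFrame(np.zeros((0, 0)))
    single = {c: _pd_at_points(model, X, (c,)) for c in names}
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        joint = _pd_at_points(model, X, (a, b))
        resid = joint - single[a] - single[b]
        strength = float(np.std(resid))
        mat.loc[a, b] = mat.loc[b, a] = strength
    return mat


def top_interactions(mat: pd.DataFrame, n: int = 4) -> list[tuple[str, str, float]]:
    """The n strongest pairs from an interaction matrix."""
    pairs = [
        (a, b, float(mat.loc[a, b]))
        for a, b in combinations(mat.index, 2)
    ]
    return sorted(pairs, key=lambda t: -t[2])[:n]


def residual_spatial_check(
    model: BRTModel, X: pd.DataFrame, y, coords, k_neighbors: int = 5,
    n_perm: int = 999, seed: int = 0,
) -> MoranResult:
    """Two-tailed Moran's I test on standardized model residuals."""
    y = np.asarray(y, float)
    resid = y - model.predict(X)
    sd = resid.std(ddof=1)
    if sd <= 1e-10 * (np.abs(y).max() + 1.0):
        raise ValueError("zero variance: constant residuals")
    standardized = (resid - resid.mean()) / sd
    return morans_i(standardized, coords, k_neighbors=k_neighbors, n_perm=n_perm, seed=seed)
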