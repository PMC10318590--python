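"""End-season yield prediction with support vector regression.

Season-long trait features (one column per trait x flight) predict plot yield
under repeated k-fold cross-validation.  Folds can be balanced on a
subpopulation label so training and testing sets keep similar population
structure; replicates of a genotype are deliberately treated as unique
entries and may co-occur across train/test.  Standardization parameters and
hyperparameters are derived strictly inside each fold's training portion, so
nothing about a test fold can influence its own predictions.

The kernel follows the kernlab convention k(u, v) = exp(-sigma * ||u - v||^2)
(sklearn's ``gamma`` is the same quantity).  The cost grid may contain the
token ``"n"``, replaced at run time by the number of feature columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from ._rng import rng_for
from .errors import DataError

log = logging.getLogger(__name__)

DEFAULT_SIGMA_GRID = (0.0001, 0.001, 0.01, 0.1)
DEFAULT_COST_GRID = (10, 50, 100, 150, 200, "n")


@dataclass
class PredictionRun:
    """Result of one repeated-CV experiment for one (year, selection)."""

    fold_r: list  #: test-fold correlations, repeats x k values
    mean_r: float
    sd_r: float
    chosen_params: list  #: dict per outer fold: repeat, fold, sigma, cost
    k: int
    repeats: int
    seed: int
    meta: dict = field(default_factory=dict)


def standardize(
    train: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Center/scale columns by training mean and sd (ddof=1).

    Zero-variance columns are dropped (logged); transforming a second matrix
    always uses the training parameters.  Raises if every column is constant.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise DataError("standardize: need a 2-D train matrix with >= 2 rows")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise DataError("standardize: all feature columns are constant")
    if not keep.all():
        log.warning("standardize: dropping %d zero-variance columns", (~keep).sum())
    params = {"mean": mu, "sd": sd, "keep": keep}
    train_z = (train[:, keep] - mu[keep]) / sd[keep]
    if apply_to is None:
        return train_z, None, params
    apply_to = np.asarray(apply_to, dtype=float)
    return train_z, (apply_to[:, keep] - mu[keep]) / sd[keep], params


def svr_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    sigma: float,
    cost: float,
    epsilon: float = 0.1,
) -> np.ndarray:
    """Epsilon-SVR with Gaussian RBF kernel; deterministic given inputs."""
    if sigma <= 0 or cost <= 0:
        raise DataError("sigma and cost must be > 0")
    model = SVR(kernel="rbf", gamma=sigma, C=cost, epsilon=epsilon)
    model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=float))
    return model.predict(np.asarray(X_test, dtype=float))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def balanced_fold_assignment(
    n: int, k: int, rng: np.random.Generator, groups: np.ndarray | None = None
) -> np.ndarray:
    """Fold index (0..k-1) per entry; within-group round-robin after shuffling.

    With ``groups`` given, each fold receives an equal number (+-1) of entries
    from every group.  A group smaller than ``k`` cannot be balanced and
    raises.
    """
    folds = np.empty(n, dtype=int)
    if groups is None:
        order = rng.permutation(n)
        folds[order] = np.arange(n) % k
        return folds
    groups = np.asarray(groups)
    start = rng.integers(0, k)  # rotate so small remainders don't pile on fold 0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < k:
            raise DataError(
                f"group {g!r} has {len(idx)} entries; cannot balance into {k} folds"
            )
        idx = rng.permutation(idx)
        folds[idx] = (np.arange(len(idx)) + start) % k
    return folds


def _resolve_cost(cost, n_features: int) -> float:
    if isinstance(cost, str):
        if cost == "n":
            return float(n_features)
        raise DataError(f"unknown cost token {cost!r}")
    return float(cost)


def _inner_search(
    X: np.ndarray,
    y: np.ndarray,
    sigma_grid,
    cost_grid,
    inner_k: int,
    epsilon: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Pick (sigma, cost) maximizing mean inner-CV correlation on (X, y)."""
    n = len(y)
    kk = min(inner_k, n)
    folds = balanced_fold_assignment(n, kk, rng)
    best = (-np.inf, None, None)
    for sigma in sigma_grid:
        for cost in cost_grid:
            c = _resolve_cost(cost, X.shape[1])
            rs = []
            for f in range(kk):
                tr, te = folds != f, folds == f
                if te.sum() < 2 or tr.sum() < 2:
                    continue
                Xtr, Xte, _ = standardize(X[tr], X[te])
                pred = svr_fit_predict(Xtr, y[tr], Xte, sigma, c, epsilon)
                r = _pearson(y[te], pred)
                if np.isfinite(r):
                    rs.append(r)
            score = np.mean(rs) if rs else -np.inf
            if score > best[0]:
                best = (score, sigma, c)
    if best[1] is None:
        raise DataError("inner grid search failed on every candidate")
    return best[1], best[2]


def grid_search_cv(
    features: pd.DataFrame | np.ndarray,
    target: np.ndarray,
    k: int = 10,
    repeats: int = 100,
    sigma_grid=DEFAULT_SIGMA_GRID,
    cost_grid=DEFAULT_COST_GRID,
    balance_groups: np.ndarray | None = None,
    seed: int = 0,
    inner_k: int = 5,
    epsilon: float = 0.1,
) -> PredictionRun:
    """Repeated k-fold CV with per-fold inner grid search.

    For every repeat, entries are shuffled into ``k`` folds (balanced on
    ``balance_groups`` when given).  Within each outer fold, an ``inner_k``-fold
    grid search on the training portion alone picks (sigma, cost); the model is
    refit on the full training portion and the Pearson correlation between
    predicted and observed yield on the test fold is recorded.  Fully
    reproducible from ``seed``.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if k < 2:
        raise DataError("k must be >= 2")
    if len(X) != len(y):
        raise DataError("features and target length mismatch")
    if len(sigma_grid) == 0 or len(cost_grid) == 0:
        raise DataError("hyperparameter grids must be nonempty")

    fold_r: list[float] = []
    chosen: list[dict] = []
    for rep in range(repeats):
        rng = rng_for(seed, "cv", rep)
        folds = balanced_fold_assignment(len(y), k, rng, balance_groups)
        for f in range(k):
            tr, te = folds != f, folds == f
            sigma, cost = _inner_search(
                X[tr], y[tr], sigma_grid, cost_grid, inner_k, epsilon, rng
            )
            Xtr, Xte, _ = standardize(X[tr], X[te])
            pred = svr_fit_predict(Xtr, y[tr], Xte, sigma, cost, epsilon)
            fold_r.append(_pearson(y[te], pred))
            chosen.append({"repeat": rep, "fold": f, "sigma": sigma, "cost": cost})
    arr = np.asarray(fold_r, dtype=float)
    ok = np.isfinite(arr)
    return PredictionRun(
        fold_r=list(arr),
        mean_r=float(arr[ok].mean()) if ok.any() else float("nan"),
        sd_r=float(arr[ok].std(ddof=1)) if ok.sum() > 1 else float("nan"),
        chosen_params=chosen,
        k=k,
        repeats=repeats,
        seed=seed,
        meta={"selection_granularity": "per_outer_fold", "inner_k": inner_k,
              "epsilon": epsilon},
    )


def feature_matrix(
    trait_table: pd.DataFrame, selection: str, trimmed: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot a long trait table into a (plot x trait-by-flight) feature matrix.

    Returns ``(features, entry_meta)`` where rows are plot entries (replicates
    kept as unique entries) and ``entry_meta`` carries plot_id, genotype, rep
    and subpopulation for fold balancing and yield joining.
    """
    sub = trait_table[
        (trait_table["selection"] == selection)
        & (trait_table["trimmed"] == trimmed)
    ]
    if sub.empty:
        raise DataError(f"no trait rows for selection {selection} trimmed={trimmed}")
    wide = sub.pivot_table(
        index="plot_id", columns=["trait", "flight_id"], values="value"
    )
    wide.columns = [f"{t}_{f}" for t, f in wide.columns]
    meta_cols = [c for c in ("genotype", "rep", "subpopulation") if c in sub.columns]
    meta = sub.groupby("plot_id")[meta_cols].first().loc[wide.index].reset_index()
    return wide.reset_index(drop=True), meta
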