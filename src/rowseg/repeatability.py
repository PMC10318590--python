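"""Entry-mean repeatability (broad-sense H2) from variance components.

The model per (trait, flight, year, selection, trim) cell is

    y_ij = mu + H_i + R_j + e_ij

with hybrid effects ``H_i ~ N(0, sigma2_H)`` random, replicate effects ``R_j``
fixed, and residuals ``e_ij ~ N(0, sigma2_E)``.  Variance components come from
restricted maximum likelihood (profile REML over the variance ratio, Brent
search); for balanced complete data the estimates coincide with the
closed-form ANOVA estimators

    sigma2_H = max(0, (MS_hybrid - MS_error)/r),   sigma2_E = MS_error,

which the fast path uses.  Entry-mean repeatability is

    H2 = sigma2_H / (sigma2_H + sigma2_E / rep).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    sigma2_H: float
    sigma2_E: float
    grand_mean: float
    rep_effects: dict
    method: str

    def __post_init__(self) -> None:
        if self.sigma2_H < 0 or self.sigma2_E <= 0:
            raise DataError("variance components out of range")


def _check_table(df: pd.DataFrame) -> pd.DataFrame:
    need = {"hybrid", "rep", "value"}
    if not need.issubset(df.columns):
        raise DataError(f"trait table needs columns {sorted(need)}")
    df = df.dropna(subset=["value"])
    if df["hybrid"].nunique() < 2:
        raise DataError("need >= 2 hybrids to estimate genetic variance")
    if df["rep"].nunique() < 2:
        raise DataError("need >= 2 replicates")
    if np.ptp(df["value"].to_numpy()) == 0:
        raise DataError("all trait values identical; variance not estimable")
    return df


def _is_balanced_complete(df: pd.DataFrame) -> bool:
    counts = df.groupby(["hybrid", "rep"]).size()
    n_h = df["hybrid"].nunique()
    n_r = df["rep"].nunique()
    return len(counts) == n_h * n_r and (counts == 1).all()


def _design(df: pd.DataFrame):
    """Response, fixed-effect design (sum-to-zero rep coding), incidence Z."""
    y = df["value"].to_numpy(dtype=float)
    reps = np.sort(df["rep"].unique())
    hybrids, h_idx = np.unique(df["hybrid"].to_numpy(), return_inverse=True)
    n = len(y)
    X = np.ones((n, len(reps)))
    for k, r in enumerate(reps[:-1]):
        col = np.where(df["rep"].to_numpy() == r, 1.0, 0.0)
        col -= np.where(df["rep"].to_numpy() == reps[-1], 1.0, 0.0)
        X[:, k + 1] = col
    Z = np.zeros((n, len(hybrids)))
    Z[np.arange(n), h_idx] = 1.0
    return y, X, Z, reps, hybrids


def _closed_form(df: pd.DataFrame) -> VarianceComponents:
    """Balanced RCB ANOVA estimators, REML-consistent at the zero boundary."""
    wide = df.pivot_table(index="hybrid", columns="rep", values="value")
    q, r = wide.shape
    y = wide.to_numpy()
    grand = y.mean()
    ss_g = r * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_r = q * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_t = ((y - grand) ** 2).sum()
    ss_e = ss_t - ss_g - ss_r
    ms_g = ss_g / (q - 1)
    ms_e = ss_e / ((q - 1) * (r - 1))
    rep_means = y.mean(axis=0)
    rep_effects = {c: rep_means[k] - grand for k, c in enumerate(wide.columns)}
    if ms_g >= ms_e:
        s2h = (ms_g - ms_e) / r
        s2e = ms_e
    else:
        # REML boundary: hybrid variance pinned at 0, residual re-estimated
        # from the fixed-effects-only model.
        s2h = 0.0
        s2e = (ss_t - ss_r) / (q * r - r)
    return VarianceComponents(
        sigma2_H=float(s2h),
        sigma2_E=float(s2e),
        grand_mean=float(grand),
        rep_effects=rep_effects,
        method="anova_closed_form",
    )


def _reml(df: pd.DataFrame, tol: float = 1e-10) -> VarianceComponents:
    """Profile REML over lambda = sigma2_H / sigma2_E (Brent on log-lambda)."""
    y, X, Z, reps, _ = _design(df)
    n, p = X.shape
    d, U = np.linalg.eigh(Z @ Z.T)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted_ll(lam: float) -> tuple[float, float, np.ndarray]:
        w = 1.0 / (1.0 + lam * d)
        XtW = Xt * w[:, None]
        A = Xt.T @ XtW
        beta = np.linalg.solve(A, XtW.T @ yt)
        resid = yt - Xt @ beta
        ypy = float(resid @ (w * resid))
        s2e = ypy / (n - p)
        sign, logdet_A = np.linalg.slogdet(A)
        ll = -0.5 * (
            (n - p) * math.log(s2e)
            + float(np.sum(np.log1p(lam * d)))
            + logdet_A
            + (n - p)
        )
        return -ll, s2e, beta

    def obj(t: float) -> float:
        return neg_restricted_ll(math.exp(t))[0]

    res = minimize_scalar(obj, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": tol})
    cand = [(neg_restricted_ll(0.0)[0], 0.0), (res.fun, math.exp(res.x))]
    lam = min(cand)[1]
    _, s2e, beta = neg_restricted_ll(lam)
    rep_effects = {}
    for k, r in enumerate(reps[:-1]):
        rep_effects[r] = float(beta[k + 1])
    rep_effects[reps[-1]] = -float(np.sum(beta[1:]))
    return VarianceComponents(
        sigma2_H=float(lam * s2e),
        sigma2_E=float(s2e),
        grand_mean=float(beta[0]),
        rep_effects=rep_effects,
        method="reml",
    )


def fit_variance_components(
    trait_values: pd.DataFrame, method: str = "auto"
) -> VarianceComponents:
    """Estimate (sigma2_H, sigma2_E) from a (hybrid, rep, value) table.

    ``method``: ``"reml"`` forces the numeric profile-REML fit, handling
    unbalanced/incomplete designs; ``"anova_closed_form"`` requires balanced
    complete data; ``"auto"`` takes the closed form when the design is balanced
    and complete (where it equals REML) and numeric REML otherwise.
    """
    df = _check_table(trait_values)
    balanced = _is_balanced_complete(df)
    if method == "anova_closed_form":
        if not balanced:
            raise DataError("closed-form estimator requires balanced complete data")
        return _closed_form(df)
    if method == "reml":
        return _reml(df)
    if method == "auto":
        return _closed_form(df) if balanced else _reml(df)
    raise DataError(f"unknown method {method!r}")


def repeatability(vc: VarianceComponents, rep: int) -> float:
    """Entry-mean H2 = sigma2_H / (sigma2_H + sigma2_E / rep), in [0, 1]."""
    if rep < 1:
        raise DataError("rep must be >= 1")
    denom = vc.sigma2_H + vc.sigma2_E / rep
    if denom == 0:
        log.warning("repeatability undefined: both variance components zero")
        return float("nan")
    return vc.sigma2_H / denom


def repeatability_sweep(
    trait_table: pd.DataFrame, method: str = "auto"
) -> pd.DataFrame:
    """One repeatability record per (trait, flight, year, selection, trim) cell.

    ``trait_table`` is the long format produced by the trait-extraction or
    trait-simulation stages: columns ``trait, year, flight_id, gdd, selection,
    trimmed, genotype (or hybrid), rep, value``.  The full Cartesian product of
    the observed factor levels is reported; an empty cell yields a
    NaN-flagged record and a log line rather than an error.
    """
    df = trait_table.rename(columns={"genotype": "hybrid"})
    levels = {
        k: sorted(df[k].unique())
        for k in ("trait", "year", "flight_id", "selection", "trimmed")
    }
    gdd_of = df.groupby("flight_id")["gdd"].first() if "gdd" in df else None
    grouped = df.groupby(["trait", "year", "flight_id", "selection", "trimmed"])
    records = []
    for combo in itertools.product(*levels.values()):
        key = dict(zip(levels.keys(), combo))
        try:
            cell = grouped.get_group(combo)
        except KeyError:
            log.warning("repeatability_sweep: empty cell %s", key)
            records.append(
                {**key, "gdd": float("nan"), "H2": float("nan"),
                 "sigma2_H": float("nan"), "sigma2_E": float("nan"), "rep": 0}
            )
            continue
        n_rep = int(cell["rep"].nunique())
        vc = fit_variance_components(cell[["hybrid", "rep", "value"]], method=method)
        records.append(
            {
                **key,
                "gdd": float(gdd_of[combo[2]]) if gdd_of is not None else float("nan"),
                "H2": repeatability(vc, n_rep),
                "sigma2_H": vc.sigma2_H,
                "sigma2_E": vc.sigma2_E,
                "rep": n_rep,
            }
        )
    return pd.DataFrame(records)
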