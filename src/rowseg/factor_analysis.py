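"""Factorial ANOVA over trim/year/row-selection and LSD letter grouping.

Repeatability (or prediction-accuracy) observations are analysed with a
fixed-effects linear model using sequential (type-I) sums of squares in the
term order trim, year, selection, selection:year — the only interaction kept,
since plot trimming is treated as a pure main effect.  Where a term is
significant, an unadjusted least-significant-difference test groups the factor
levels with shared letters at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DataError

log = logging.getLogger(__name__)

DEFAULT_TERMS = ("trim", "year", "selection", "selection:year")


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_factorial(
    observations: pd.DataFrame,
    response: str = "H2",
    terms: tuple[str, ...] = DEFAULT_TERMS,
) -> pd.DataFrame:
    """Type-I ANOVA table (term, df, sum_sq, mean_sq, F, p, stars).

    ``observations`` must hold the response column plus every factor named in
    ``terms`` (interactions written ``a:b``).  Factors are treated as
    categorical.  An empty cell for a tested interaction raises, naming the
    cell.  A constant response returns F=0, p=1 for every term.
    """
    factors = sorted({f for t in terms for f in t.split(":")})
    for f in factors:
        if f not in observations.columns:
            raise DataError(f"anova_factorial: missing factor column {f!r}")
    if response not in observations.columns:
        raise DataError(f"anova_factorial: missing response column {response!r}")
    df = observations.dropna(subset=[response]).copy()
    for t in terms:
        parts = t.split(":")
        if len(parts) > 1:
            sizes = df.groupby(parts, observed=True).size()
            full = np.prod([df[p].nunique() for p in parts])
            if len(sizes) < full:
                have = set(map(tuple, sizes.index.to_list())) if len(parts) > 1 else set(sizes.index)
                allc = set(itertools.product(*[df[p].unique() for p in parts]))
                missing = sorted(allc - have)[0]
                raise DataError(f"anova_factorial: empty cell {dict(zip(parts, missing))}")

    y = df[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        rows = []
        for t in terms:
            parts = t.split(":")
            dof = int(np.prod([df[p].nunique() - 1 for p in parts]))
            rows.append({"term": t, "df": dof, "sum_sq": 0.0, "mean_sq": 0.0,
                         "F": 0.0, "p": 1.0, "stars": ""})
        resid_df = len(df) - 1 - sum(r["df"] for r in rows)
        rows.append({"term": "Residual", "df": resid_df, "sum_sq": 0.0,
                     "mean_sq": 0.0, "F": np.nan, "p": np.nan, "stars": ""})
        return pd.DataFrame(rows)

    df = df.rename(columns={response: "_resp"})
    formula = "_resp ~ " + " + ".join(
        ":".join(f"C({p})" for p in t.split(":")) for t in terms
    )
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    out = []
    for name, row in table.iterrows():
        term = (
            "Residual"
            if name == "Residual"
            else ":".join(p[2:-1] for p in name.split(":"))  # strip C(...)
        )
        p = float(row["PR(>F)"]) if np.isfinite(row["F"]) else np.nan
        out.append(
            {
                "term": term,
                "df": int(row["df"]),
                "sum_sq": float(row["sum_sq"]),
                "mean_sq": float(row["sum_sq"]) / row["df"] if row["df"] else np.nan,
                "F": float(row["F"]) if np.isfinite(row["F"]) else np.nan,
                "p": p,
                "stars": _stars(p) if name != "Residual" else "",
            }
        )
    return pd.DataFrame(out)


@dataclass
class LsdGrouping:
    """LSD means separation for one factor."""

    means: pd.Series  #: level -> mean, descending
    letters: dict  #: level -> letter string
    lsd: float
    alpha: float
    n_per_level: float


def _assign_letters(means: pd.Series, lsd: float) -> dict:
    """Shared-letter grouping: levels share a letter iff |diff| <= lsd.

    Standard insertion algorithm on descending means: each maximal run of
    mutually non-significant levels gets one letter; runs nested inside an
    earlier run are skipped.
    """
    levels = list(means.index)
    vals = means.to_numpy()
    n = len(levels)
    runs: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n and abs(vals[i] - vals[j + 1]) <= lsd:
            j += 1
        if not runs or j > runs[-1][1]:
            runs.append((i, j))
    letters = {lv: "" for lv in levels}
    for letter_idx, (a, b) in enumerate(runs):
        ch = chr(ord("a") + letter_idx)
        for k in range(a, b + 1):
            letters[levels[k]] += ch
    return letters


def lsd_test(
    observations: pd.DataFrame,
    factor: str,
    response: str = "H2",
    mse: float | None = None,
    df_error: int | None = None,
    alpha: float = 0.05,
) -> LsdGrouping:
    """Least-significant-difference grouping of factor levels.

    ``mse`` and ``df_error`` normally come from a preceding
    :func:`anova_factorial`; when omitted, a one-way ANOVA on ``factor`` alone
    supplies them.  Unbalanced level sizes use the harmonic mean n (logged).
    LSD = t(1 - alpha/2, df_error) * sqrt(2 * MSE / n).
    """
    df = observations.dropna(subset=[response])
    sizes = df.groupby(factor, observed=True).size()
    if (sizes < 1).any() or len(sizes) < 2:
        raise DataError("lsd_test: need >= 2 populated levels")
    if mse is None or df_error is None:
        table = anova_factorial(df, response=response, terms=(factor,))
        resid = table[table["term"] == "Residual"].iloc[0]
        mse = float(resid["mean_sq"])
        df_error = int(resid["df"])
    if df_error < 1:
        raise DataError("lsd_test: df_error < 1")
    if sizes.nunique() > 1:
        n_eff = len(sizes) / np.sum(1.0 / sizes.to_numpy())
        log.warning("lsd_test: unbalanced levels, using harmonic mean n=%.2f", n_eff)
    else:
        n_eff = float(sizes.iloc[0])
    lsd = float(
        stats.t.ppf(1 - alpha / 2, df_error) * np.sqrt(2.0 * mse / n_eff)
    )
    means = (
        df.groupby(factor, observed=True)[response]
        .mean()
        .sort_values(ascending=False, kind="mergesort")
    )
    letters = _assign_letters(means, lsd)
    return LsdGrouping(
        means=means, letters=letters, lsd=lsd, alpha=alpha, n_per_level=n_eff
    )


def lsd_report(grouping: LsdGrouping, factor: str) -> pd.DataFrame:
    """Letter-annotated means table (one row per level, descending mean)."""
    return pd.DataFrame(
        {
            factor: grouping.means.index,
            "mean": grouping.means.to_numpy(),
            "letters": [grouping.letters[lv] for lv in grouping.means.index],
        }
    )
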