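"""Factorial ANOVA and LSD letter grouping against linear-algebra oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rowseg import anova_factorial, lsd_test
from rowseg.errors import DataError
from rowseg.factor_analysis import lsd_report


def _dataset(rng, sel_effects=None, trim_effect=0.0, noise=0.1, n_rep=4, years=(1, 2)):
    sel_effects = sel_effects or {}
    rows = []
    for sel in ("RS1234", "RS23", "RS14", "RS1", "RS2", "RS3", "RS4"):
        for trim in (False, True):
            for year in years:
                for k in range(n_rep):
                    rows.append(
                        {
                            "selection": sel,
                            "trimmed": trim,
                            "year": year,
                            "H2": 0.6
                            + sel_effects.get(sel, 0.0)
                            + (trim_effect if trim else 0.0)
                            + 0.05 * (year - 1)
                            + rng.normal(0, noise),
                        }
                    )
    return pd.DataFrame(rows)


def anova_oracle(df, terms, response="H2"):
    """Sequential SS by explicit projection matrices."""
    y = df[response].to_numpy(dtype=float)
    n = len(y)

    def dummies(term):
        parts = term.split(":")
        lab = df[parts[0]].astype(str)
        for p in parts[1:]:
            lab = lab + "|" + df[p].astype(str)
        return pd.get_dummies(lab).to_numpy(dtype=float)

    X = np.ones((n, 1))
    results = {}
    rss_prev = y @ y - (y.sum() ** 2) / n  # SS around the mean
    df_prev = n - 1
    for term in terms:
        X = np.column_stack([X, dummies(term)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = resid @ resid
        rank = np.linalg.matrix_rank(X)
        results[term] = (rss_prev - rss, df_prev - (n - rank))
        rss_prev, df_prev = rss, n - rank
    results["Residual"] = (rss_prev, df_prev)
    return results


def test_anova_matches_projection_oracle():
    rng = np.random.default_rng(2)
    df = _dataset(rng, sel_effects={"RS1": -0.2, "RS23": 0.1})
    terms = ("trimmed", "year", "selection", "selection:year")
    table = anova_factorial(df, terms=terms).set_index("term")
    oracle = anova_oracle(df, terms)
    for term, (ss, dof) in oracle.items():
        assert table.loc[term, "sum_sq"] == pytest.approx(ss, rel=1e-8)
        assert table.loc[term, "df"] == dof
    mse = oracle["Residual"][0] / oracle["Residual"][1]
    f_sel = (oracle["selection"][0] / oracle["selection"][1]) / mse
    assert table.loc["selection", "F"] == pytest.approx(f_sel, rel=1e-8)


def test_anova_sum_of_squares_conservation():
    rng = np.random.default_rng(3)
    df = _dataset(rng)
    table = anova_factorial(df, terms=("trimmed", "year", "selection", "selection:year"))
    y = df["H2"].to_numpy()
    total = ((y - y.mean()) ** 2).sum()
    assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-8)


def test_constant_response_documented_degenerate_behavior():
    rng = np.random.default_rng(4)
    df = _dataset(rng, noise=0.0)
    df["H2"] = 0.5
    table = anova_factorial(df, terms=("trimmed", "selection")).set_index("term")
    assert (table.loc[["trimmed", "selection"], "F"] == 0).all()
    assert (table.loc[["trimmed", "selection"], "p"] == 1).all()


def test_empty_interaction_cell_is_named():
    rng = np.random.default_rng(5)
    df = _dataset(rng)
    df = df[~((df.selection == "RS4") & (df.year == 2))]
    with pytest.raises(DataError, match="RS4"):
        anova_factorial(df, terms=("year", "selection", "selection:year"))


def test_power_and_null_calibration():
    """Built-in selection effect is detected; trim null rejects ~ alpha."""
    rng = np.random.default_rng(6)
    p_sel, p_trim = [], []
    for _ in range(60):
        df = _dataset(rng, sel_effects={"RS1": -0.15, "RS4": -0.15, "RS14": -0.15},
                      noise=0.05, n_rep=3)
        t = anova_factorial(df, terms=("trimmed", "year", "selection")).set_index("term")
        p_sel.append(t.loc["selection", "p"])
        p_trim.append(t.loc["trimmed", "p"])
    assert np.mean(np.array(p_sel) < 0.05) >= 0.9
    assert np.mean(np.array(p_trim) < 0.05) <= 0.18  # ~5% nominal + MC error


def test_lsd_two_levels_separate_and_all_equal_share():
    df = pd.DataFrame(
        {"g": ["a"] * 6 + ["b"] * 6, "H2": [1.0] * 6 + [2.0] * 6}
    )
    df["H2"] += np.random.default_rng(0).normal(0, 0.01, 12)
    res = lsd_test(df, "g")
    assert res.letters[df.groupby("g")["H2"].mean().idxmax()] == "a"
    assert len(set(res.letters.values())) == 2

    same = pd.DataFrame({"g": list("aabbcc"), "H2": [1, 1.01, 1.0, 0.99, 1.0, 1.02]})
    res2 = lsd_test(same, "g")
    assert set(res2.letters.values()) == {"a"}


def pairwise_oracle(means, lsd):
    """Levels are 'not different' iff |diff| <= LSD; compare via shared letters."""
    sig = {}
    for a, b in itertools.combinations(means.index, 2):
        sig[(a, b)] = abs(means[a] - means[b]) > lsd
    return sig


def test_lsd_letters_reproduce_all_pairs_decisions():
    rng = np.random.default_rng(8)
    df = _dataset(rng, sel_effects={"RS1": -0.25, "RS4": -0.22, "RS14": -0.20,
                                    "RS23": 0.05}, noise=0.04)
    res = lsd_test(df, "selection")
    oracle = pairwise_oracle(res.means, res.lsd)
    for (a, b), different in oracle.items():
        shares = bool(set(res.letters[a]) & set(res.letters[b]))
        assert shares != different, (a, b)


def test_lsd_explicit_t_formula():
    rng = np.random.default_rng(9)
    df = _dataset(rng, noise=0.05)
    table = anova_factorial(df, terms=("selection",)).set_index("term")
    mse, dfe = table.loc["Residual", "mean_sq"], int(table.loc["Residual", "df"])
    res = lsd_test(df, "selection", mse=mse, df_error=dfe)
    n = len(df) / df["selection"].nunique()
    assert res.lsd == pytest.approx(
        stats.t.ppf(0.975, dfe) * np.sqrt(2 * mse / n), rel=1e-12
    )


def test_lsd_invariant_to_input_ordering():
    rng = np.random.default_rng(10)
    df = _dataset(rng, sel_effects={"RS1": -0.3})
    a = lsd_test(df, "selection")
    b = lsd_test(df.sample(frac=1, random_state=1), "selection")
    assert a.letters == b.letters
    rep = lsd_report(a, "selection")
    assert list(rep["mean"]) == sorted(rep["mean"], reverse=True)
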