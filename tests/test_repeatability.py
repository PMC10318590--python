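"""Variance components and entry-mean repeatability."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from rowseg import fit_variance_components, repeatability, repeatability_sweep
from rowseg.errors import DataError
from rowseg.repeatability import VarianceComponents

from conftest import balanced_table


def closed_form_oracle(df):
    """Brute-force RCB ANOVA mean squares -> variance components."""
    wide = df.pivot(index="hybrid", columns="rep", values="value").to_numpy()
    q, r = wide.shape
    grand = wide.mean()
    ms_g = r * ((wide.mean(axis=1) - grand) ** 2).sum() / (q - 1)
    ss_t = ((wide - grand) ** 2).sum()
    ss_r = q * ((wide.mean(axis=0) - grand) ** 2).sum()
    ss_g = ms_g * (q - 1)
    ms_e = (ss_t - ss_g - ss_r) / ((q - 1) * (r - 1))
    return max(0.0, (ms_g - ms_e) / r), ms_e


@pytest.mark.parametrize(
    "s2h,s2e,rep,expected",
    [(1, 1, 2, 2 / 3), (0, 1, 2, 0.0), (1, 3, 3, 0.5), (4, 1, 1, 0.8)],
)
def test_repeatability_formula(s2h, s2e, rep, expected):
    vc = VarianceComponents(s2h, s2e, 0.0, {}, "test")
    assert repeatability(vc, rep) == pytest.approx(expected)


def test_repeatability_monotone_in_rep_and_signal():
    vc = VarianceComponents(1.0, 2.0, 0.0, {}, "test")
    h = [repeatability(vc, r) for r in (1, 2, 3, 10)]
    assert all(b > a for a, b in zip(h, h[1:]))
    more_signal = VarianceComponents(2.0, 2.0, 0.0, {}, "test")
    assert repeatability(more_signal, 2) > repeatability(vc, 2)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_reml_equals_closed_form_on_balanced_data(seed):
    rng = np.random.default_rng(seed)
    df = balanced_table(40, 2, s2h=2.0, s2e=1.0, rng=rng,
                        rep_offsets=[0.0, 0.5])
    reml = fit_variance_components(df, method="reml")
    cf = fit_variance_components(df, method="anova_closed_form")
    oracle_h, oracle_e = closed_form_oracle(df)
    assert reml.sigma2_H == pytest.approx(cf.sigma2_H, rel=1e-6)
    assert reml.sigma2_E == pytest.approx(cf.sigma2_E, rel=1e-6)
    assert cf.sigma2_H == pytest.approx(oracle_h, rel=1e-10)
    assert cf.sigma2_E == pytest.approx(oracle_e, rel=1e-10)


def test_auto_method_dispatch(rng):
    df = balanced_table(20, 2, 1.0, 1.0, rng)
    assert fit_variance_components(df).method == "anova_closed_form"
    assert fit_variance_components(df.iloc[1:]).method == "reml"


def test_zero_signal_hits_boundary(rng):
    df = balanced_table(30, 3, s2h=0.0, s2e=1.0, rng=rng)
    vc = fit_variance_components(df, method="reml")
    assert vc.sigma2_H >= 0.0
    assert repeatability(vc, 3) < 0.5


def test_reml_handles_missing_plots(rng):
    df = balanced_table(50, 2, 2.0, 1.0, rng).drop(index=[0, 7, 53])
    vc = fit_variance_components(df, method="reml")
    assert 0.5 < vc.sigma2_H < 5.0
    assert 0.3 < vc.sigma2_E < 3.0


def test_parameter_recovery_small_monte_carlo():
    # true H2 = 2 / (2 + 1/2) = 0.8; mean over 40 balanced trials
    rng = np.random.default_rng(99)
    h2 = []
    for _ in range(40):
        df = balanced_table(200, 2, 2.0, 1.0, rng)
        vc = fit_variance_components(df)
        h2.append(repeatability(vc, 2))
    assert np.mean(h2) == pytest.approx(0.8, abs=0.03)


@pytest.mark.parametrize(
    "bad", [
        pd.DataFrame({"hybrid": ["a"] * 4, "rep": [1, 1, 2, 2], "value": [1, 2, 3, 4]}),
        pd.DataFrame({"hybrid": list("abab"), "rep": [1, 1, 2, 2], "value": [1.0] * 4}),
    ],
)
def test_degenerate_tables_raise(bad):
    with pytest.raises(DataError):
        fit_variance_components(bad)


def test_sweep_produces_full_cartesian_grid(tiny_obs):
    records = repeatability_sweep(tiny_obs)
    # 1 trait x 1 year x 2 flights x 7 selections x 2 trims
    assert len(records) == 28
    assert records["H2"].between(0, 1).all()
    again = repeatability_sweep(tiny_obs)
    pd.testing.assert_frame_equal(records, again)


def test_sweep_flags_empty_cells(tiny_obs):
    holey = tiny_obs[
        ~((tiny_obs.selection == "RS1") & (tiny_obs.flight_id == "F01"))
    ]
    records = repeatability_sweep(holey)
    assert len(records) == 28
    gap = records[(records.selection == "RS1") & (records.flight_id == "F01")]
    assert gap["H2"].isna().all()


def test_inner_rows_more_repeatable_than_border_row(tiny_obs):
    records = repeatability_sweep(tiny_obs)
    mean_by_sel = records.groupby("selection")["H2"].mean()
    assert mean_by_sel["RS23"] > mean_by_sel["RS1"]


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_reml_matches_lme4_on_unbalanced_fixture(tmp_path, rng):
    """Independent oracle: lme4 REML on the same unbalanced table."""
    df = balanced_table(30, 3, 1.5, 0.8, rng, rep_offsets=[0.0, 0.3, -0.2]).drop(index=[2, 11, 40])
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(value ~ factor(rep) + (1|hybrid), data = d, REML = TRUE)
        vc <- as.data.frame(VarCorr(m))
        cat(vc$vcov[vc$grp == "hybrid"], vc$vcov[vc$grp == "Residual"], sep = "\\n")
    """))
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    lme4_h, lme4_e = map(float, out.stdout.split())
    vc = fit_variance_components(df, method="reml")
    assert vc.sigma2_H == pytest.approx(lme4_h, rel=1e-4)
    assert vc.sigma2_E == pytest.approx(lme4_e, rel=1e-4)
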