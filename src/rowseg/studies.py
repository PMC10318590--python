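"""Replicated simulation studies over the synthetic trial generator.

These are the package's headline experiments: how accurately REML recovers
entry-mean repeatability at trial scale, whether the border-effect structure
in the generator reproduces the expected ordering of row-selection schemes
(inner rows most repeatable, border rows least, trimming null), and whether
yield prediction from inner-row features beats border-row features when yield
is truly driven by the inner rows.  Each study is deterministic given its seed
and returns plain dictionaries ready for serialization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import rng_for
from .factor_analysis import anova_factorial
from .repeatability import fit_variance_components, repeatability, repeatability_sweep
from .synthetic_field import TrialConfig, simulate_trait_observations, simulate_trial
from .yield_prediction import feature_matrix, grid_search_cv


def h2_recovery_study(
    n_trials: int = 200,
    n_genotypes: int = 200,
    n_reps: int = 2,
    sigma2_H: float = 2.0,
    sigma2_E: float = 1.0,
    seed: int = 0,
    method: str = "reml",
) -> dict:
    """Monte-Carlo recovery of entry-mean H2 on balanced RCB designs.

    True H2 = sigma2_H / (sigma2_H + sigma2_E / n_reps); each trial draws
    genotype effects, fixed replicate offsets, and residuals, fits variance
    components, and records the H2 estimate.
    """
    true_h2 = sigma2_H / (sigma2_H + sigma2_E / n_reps)
    estimates = []
    for t in range(n_trials):
        rng = rng_for(seed, "recovery", t)
        g = rng.normal(0.0, np.sqrt(sigma2_H), n_genotypes)
        rep_off = rng.normal(0.0, 0.3, n_reps)
        rows = []
        for j in range(n_reps):
            vals = g + rep_off[j] + rng.normal(0.0, np.sqrt(sigma2_E), n_genotypes)
            rows.append(
                pd.DataFrame(
                    {"hybrid": np.arange(n_genotypes), "rep": j + 1, "value": vals}
                )
            )
        vc = fit_variance_components(pd.concat(rows, ignore_index=True), method=method)
        estimates.append(repeatability(vc, n_reps))
    return {
        "true_h2": true_h2,
        "mean_h2": float(np.mean(estimates)),
        "sd_h2": float(np.std(estimates, ddof=1)),
        "n_trials": n_trials,
        "estimates": estimates,
    }


def border_effect_study(
    n_trials: int = 50,
    n_genotypes: int = 100,
    n_reps: int = 2,
    years: int = 2,
    flight_gdds=(300.0, 500.0, 750.0, 1000.0),
    alpha: float = 0.05,
    seed: int = 0,
    trial_overrides: dict | None = None,
) -> dict:
    """Repeatability ordering and ANOVA calibration under border effects.

    Each trial simulates ``years`` independent field years with positive
    border mean shift and extra border noise, runs the repeatability sweep over
    all seven row selections and both trim variants, and performs the
    trim/year/selection factorial ANOVA with flights as replicates.  Reports
    mean H2 per selection, the rate at which the selection effect is detected
    at ``alpha``, and the rejection rate of the (truly null) trim effect.
    """
    overrides = {"n_genotypes": n_genotypes, "n_reps": n_reps, "plants_per_row": 2}
    overrides.update(trial_overrides or {})
    h2_frames = []
    p_sel, p_trim = [], []
    for t in range(n_trials):
        obs_frames = []
        for year in range(1, years + 1):
            cfg = TrialConfig(
                **overrides,
                rng_seed=int(rng_for(seed, "border", t, year).integers(0, 2**31 - 1)),
            )
            trial = simulate_trial(cfg)
            obs_frames.append(
                simulate_trait_observations(trial, flight_gdds, year=year)
            )
        h2 = repeatability_sweep(pd.concat(obs_frames, ignore_index=True))
        h2["trial"] = t
        h2_frames.append(h2)
        terms = (
            ("trimmed", "year", "selection", "selection:year")
            if years > 1
            else ("trimmed", "selection")
        )
        table = anova_factorial(h2.dropna(subset=["H2"]), terms=terms).set_index("term")
        p_sel.append(float(table.loc["selection", "p"]))
        p_trim.append(float(table.loc["trimmed", "p"]))
    allh2 = pd.concat(h2_frames, ignore_index=True)
    mean_by_sel = allh2.groupby("selection")["H2"].mean()
    return {
        "mean_h2_by_selection": mean_by_sel.to_dict(),
        "selection_detection_rate": float(np.mean(np.asarray(p_sel) < alpha)),
        "trim_rejection_rate": float(np.mean(np.asarray(p_trim) < alpha)),
        "n_trials": n_trials,
    }


def prediction_direction_study(
    n_trials: int = 20,
    n_genotypes: int = 50,
    n_reps: int = 2,
    flight_gdds=(300.0, 500.0, 750.0),
    selections=("RS23", "RS14"),
    k: int = 5,
    repeats: int = 10,
    sigma_grid=(0.01, 0.1),
    cost_grid=(10, 100),
    seed: int = 0,
) -> dict:
    """Cross-validated yield-prediction accuracy per row selection.

    Yield in the generator is a function of the inner-row latent means, so
    features from the inner selection should out-predict features from the
    border selection.  Returns mean CV correlation per selection and the
    fraction of trials where the first selection beats the second.
    """
    mean_r: dict[str, list[float]] = {s: [] for s in selections}
    for t in range(n_trials):
        cfg = TrialConfig(
            n_genotypes=n_genotypes,
            n_reps=n_reps,
            plants_per_row=2,
            rng_seed=int(rng_for(seed, "pred", t).integers(0, 2**31 - 1)),
        )
        trial = simulate_trial(cfg)
        obs = simulate_trait_observations(
            trial, flight_gdds, selections=selections, trims=(False,)
        )
        yield_by_plot = trial.yield_table.set_index("plot_id")["yield_value"]
        for sel in selections:
            feats, meta = feature_matrix(obs, sel, trimmed=False)
            target = yield_by_plot.loc[meta["plot_id"]].to_numpy()
            run = grid_search_cv(
                feats,
                target,
                k=k,
                repeats=repeats,
                sigma_grid=sigma_grid,
                cost_grid=cost_grid,
                balance_groups=meta["subpopulation"].to_numpy(),
                seed=int(rng_for(seed, "pred-cv", t, sel).integers(0, 2**31 - 1)),
            )
            mean_r[sel].append(run.mean_r)
    first, second = selections[0], selections[1]
    wins = np.mean(np.asarray(mean_r[first]) > np.asarray(mean_r[second]))
    return {
        "mean_r_by_selection": {s: float(np.mean(v)) for s, v in mean_r.items()},
        "win_fraction": float(wins),
        "per_trial_r": {s: list(map(float, v)) for s, v in mean_r.items()},
        "n_trials": n_trials,
    }
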