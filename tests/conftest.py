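import numpy as np
import pandas as pd
import pytest

from rowseg import TrialConfig, simulate_trial, simulate_trait_observations
from rowseg.plot_geometry import build_grid
from rowseg.synthetic_field import render_point_cloud, render_rasters


@pytest.fixture(scope="session")
def tiny_trial():
    """10 genotypes x 2 reps, default geometry and effect sizes."""
    return simulate_trial(TrialConfig(n_genotypes=10, n_reps=2, plants_per_row=8, rng_seed=11))


@pytest.fixture(scope="session")
def tiny_boxes(tiny_trial):
    return build_grid(tiny_trial.plants)


@pytest.fixture(scope="session")
def tiny_cloud(tiny_trial):
    """Mid-season point cloud with truth labels."""
    return render_point_cloud(tiny_trial, 600.0, ground_spacing_m=0.2)


@pytest.fixture(scope="session")
def tiny_rasters(tiny_trial):
    return render_rasters(tiny_trial, 600.0, rgb_gsd=0.03, hs_gsd=0.08)


@pytest.fixture(scope="session")
def tiny_obs(tiny_trial):
    """Simulated trait observations for two flights, all selections/trims."""
    return simulate_trait_observations(tiny_trial, [300.0, 700.0])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def balanced_table(n_geno, n_rep, s2h, s2e, rng, rep_offsets=None):
    """Simulated balanced (hybrid, rep, value) table for variance components."""
    g = rng.normal(0, np.sqrt(s2h), n_geno)
    rows = []
    for j in range(n_rep):
        off = 0.0 if rep_offsets is None else rep_offsets[j]
        vals = 10.0 + g + off + rng.normal(0, np.sqrt(s2e), n_geno)
        for i in range(n_geno):
            rows.append({"hybrid": f"g{i}", "rep": j + 1, "value": vals[i]})
    return pd.DataFrame(rows)
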