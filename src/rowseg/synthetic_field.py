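"""Synthetic four-row-plot field trial with known ground truth.

The generator emulates a randomized complete block (RCB) trial of multi-row
plots with the statistical structure the downstream analysis assumes:

* a latent per-row "canopy vigor" trait, ``latent = mu + G_i + R_j + border + e``,
  with genotype effects ``G_i ~ N(0, genetic_variance)``, fixed replicate
  offsets ``R_j``, a mean shift plus extra noise on the two border rows
  (rows 1 and 4), and row-level residuals;
* end-season yield generated from the *inner* rows (2 and 3) only, mirroring
  trials that harvest the two center rows of a four-row plot;
* renderers that turn the latent truth into LiDAR-like point clouds and
  RGB / hyperspectral rasters, plus a direct trait-observation simulator for
  large replicated studies.

Geometry defaults: 3.05 m rows, 0.76 m row spacing, 0.76 m alleys.
Everything is a pure function of the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from ._rng import rng_for
from .errors import ConfigError
from .plot_geometry import ROW_SELECTIONS
from .raster import Raster

#: Band centers (nm) required by the vegetation-index formulary.
WAVELENGTHS_NM = np.array(
    [420, 445, 500, 531, 550, 570, 670, 680, 695, 700, 705, 720, 740, 750, 800],
    dtype=float,
)

#: Template soil reflectance: featureless, slowly rising with wavelength.
SOIL_SPECTRUM = 0.18 + 0.0003 * (WAVELENGTHS_NM - 420.0)

#: Template vegetation reflectance: green bump, red absorption, red edge, NIR plateau.
VEG_SPECTRUM = np.array(
    [0.04, 0.04, 0.06, 0.08, 0.10, 0.09, 0.04, 0.04, 0.05, 0.06, 0.08, 0.18, 0.35, 0.45, 0.50]
)

#: Index of the first "NIR-side" band (>= 720 nm) whose reflectance scales with vigor.
_NIR_MASK = WAVELENGTHS_NM >= 720.0


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of one synthetic trial.

    Trait units are arbitrary "canopy vigor" units centered on ``trait_mean``;
    heights and spectra are derived from the latent value at render time.
    """

    n_genotypes: int = 100
    n_reps: int = 2
    rows_per_plot: int = 4
    row_spacing_m: float = 0.76
    row_length_m: float = 3.05
    alley_m: float = 0.76
    plants_per_row: int = 15
    trait_mean: float = 1.0
    genetic_variance: float = 0.04
    residual_variance: float = 0.01
    border_effect_mean_shift: float = 0.15
    border_extra_sd: float = 0.10
    alley_end_shift: float = 0.10
    end_zone_m: float = 0.40
    yield_noise_sd: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genotypes": self.n_genotypes,
            "n_reps": self.n_reps,
            "rows_per_plot": self.rows_per_plot,
            "plants_per_row": self.plants_per_row,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        lengths = {
            "row_spacing_m": self.row_spacing_m,
            "row_length_m": self.row_length_m,
            "alley_m": self.alley_m,
        }
        for name, v in lengths.items():
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v!r}")
        nonneg = {
            "genetic_variance": self.genetic_variance,
            "residual_variance": self.residual_variance,
            "border_extra_sd": self.border_extra_sd,
            "yield_noise_sd": self.yield_noise_sd,
            "end_zone_m": self.end_zone_m,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v!r}")

    @property
    def plot_pitch_x(self) -> float:
        """Longitudinal footprint of one plot incl. its alley."""
        return self.row_length_m + self.alley_m

    @property
    def plot_pitch_y(self) -> float:
        """Lateral footprint of one plot (all rows at full spacing)."""
        return self.rows_per_plot * self.row_spacing_m


@dataclass
class FieldTrial:
    """A simulated trial: layout, latent truth, plants, and yield."""

    config: TrialConfig
    plots: pd.DataFrame  #: plot_id, genotype, rep, subpopulation, range_idx, col_idx, x0, y0
    truth: pd.DataFrame  #: plot_id, row_index, latent
    plants: pd.DataFrame  #: plot_id, row_index, plant_idx, x, y, end_zone
    yield_table: pd.DataFrame  #: plot_id, yield_value

    def row_line_y(self, plot_row: pd.Series, row_index: int) -> float:
        c = self.config
        return float(plot_row["y0"] + (row_index - 0.5) * c.row_spacing_m)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.plots.to_csv(outdir / "plots.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.plants.to_csv(outdir / "plants.csv", index=False)
        self.yield_table.to_csv(outdir / "yield.csv", index=False)
        cfg_lines = [f"{k}: {v}" for k, v in asdict(self.config).items()]
        (outdir / "trial_config.yaml").write_text("\n".join(cfg_lines) + "\n")


# ---------------------------------------------------------------------------
# Trial simulation

def _field_layout(config: TrialConfig) -> tuple[int, int]:
    """(ranges per replicate block, plot columns per block) — roughly square."""
    block_cols = max(1, math.ceil(math.sqrt(config.n_genotypes)))
    n_ranges = math.ceil(config.n_genotypes / block_cols)
    return n_ranges, block_cols

# Yield model: linear, monotone in the mean latent of the two inner rows.
YIELD_INTERCEPT = 2.0
YIELD_SLOPE = 10.0


def simulate_trial(config: TrialConfig) -> FieldTrial:
    """Draw one trial: RCB layout, latent row truth, plant positions, yield.

    Within each replicate block the genotype-to-plot assignment is an
    independent random permutation; every genotype appears exactly once per
    block.  Latent row truth follows the border-effect model in the module
    docstring; yield is ``YIELD_INTERCEPT + YIELD_SLOPE * mean(latent rows 2,3)``
    plus ``N(0, yield_noise_sd^2)`` noise.
    """
    c = config
    rng = rng_for(c.rng_seed, "trial")
    n_ranges, block_cols = _field_layout(c)

    genetic = rng.normal(0.0, math.sqrt(c.genetic_variance), size=c.n_genotypes)
    rep_offsets = rng.normal(0.0, 0.05, size=c.n_reps)  # fixed replicate effects
    subpop = np.where(np.arange(c.n_genotypes) % 2 == 0, "temperate", "tropical")

    rows = []
    for j in range(c.n_reps):
        order = rng.permutation(c.n_genotypes)
        for slot, g in enumerate(order):
            rr, cc = divmod(slot, block_cols)
            rows.append(
                {
                    "plot_id": f"P{j + 1:02d}_{rr + 1:03d}_{cc + 1:02d}",
                    "genotype": f"G{g + 1:04d}",
                    "rep": j + 1,
                    "subpopulation": subpop[g],
                    "range_idx": rr,
                    "col_idx": cc,
                    "x0": rr * c.plot_pitch_x,
                    "y0": (j * block_cols + cc) * c.plot_pitch_y,
                    "genetic_value": genetic[g],
                    "rep_offset": rep_offsets[j],
                }
            )
    plots = pd.DataFrame(rows)

    border = {1, c.rows_per_plot} if c.rows_per_plot > 1 else set()
    truth_rows = []
    for _, p in plots.iterrows():
        for r in range(1, c.rows_per_plot + 1):
            is_border = r in border
            sd = math.sqrt(
                c.residual_variance + (c.border_extra_sd**2 if is_border else 0.0)
            )
            latent = (
                c.trait_mean
                + p["genetic_value"]
                + p["rep_offset"]
                + (c.border_effect_mean_shift if is_border else 0.0)
                + rng.normal(0.0, sd)
            )
            truth_rows.append(
                {"plot_id": p["plot_id"], "row_index": r, "latent": latent}
            )
    truth = pd.DataFrame(truth_rows)

    plants = _place_plants(c, plots, rng)

    inner = [r for r in range(1, c.rows_per_plot + 1) if r not in border] or list(
        range(1, c.rows_per_plot + 1)
    )
    inner_mean = (
        truth[truth["row_index"].isin(inner)].groupby("plot_id")["latent"].mean()
    )
    yield_table = pd.DataFrame(
        {
            "plot_id": inner_mean.index,
            "yield_value": YIELD_INTERCEPT
            + YIELD_SLOPE * inner_mean.to_numpy()
            + rng.normal(0.0, c.yield_noise_sd, size=len(inner_mean)),
        }
    ).reset_index(drop=True)

    return FieldTrial(config=c, plots=plots, truth=truth, plants=plants, yield_table=yield_table)


def _place_plants(c: TrialConfig, plots: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Regularly spaced plants along each row with N(0, 2 cm) jitter."""
    n = c.plants_per_row
    nominal = np.linspace(0.0, c.row_length_m, n)
    out = []
    for _, p in plots.iterrows():
        for r in range(1, c.rows_per_plot + 1):
            jitter = rng.normal(0.0, 0.02, size=n)
            x = np.clip(nominal + jitter, 0.0, c.row_length_m) + p["x0"]
            y = p["y0"] + (r - 0.5) * c.row_spacing_m + rng.normal(0.0, 0.01, size=n)
            dist_end = np.minimum(x - p["x0"], p["x0"] + c.row_length_m - x)
            for k in range(n):
                out.append(
                    {
                        "plot_id": p["plot_id"],
                        "row_index": r,
                        "plant_idx": k,
                        "x": x[k],
                        "y": y[k],
                        "end_zone": bool(dist_end[k] <= c.end_zone_m),
                    }
                )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Growth and rendering

def growth_scale(flight_gdd: float, half_sat_gdd: float = 300.0) -> float:
    """Saturating canopy growth multiplier in [0, 1): 0 at emergence."""
    if flight_gdd < 0:
        raise ConfigError("flight_gdd must be >= 0")
    return flight_gdd / (flight_gdd + half_sat_gdd)

#: Reference mature canopy height (m) for a latent value of 1.
REF_HEIGHT_M = 3.0
#: Reference canopy radius (m) for a latent value of 1 at full growth.
REF_RADIUS_M = 0.22
#: Canopy points per plant at full growth, latent 1.
REF_POINTS_PER_PLANT = 60


def render_point_cloud(
    trial: FieldTrial,
    flight_gdd: float,
    seed: int | None = None,
    ground_spacing_m: float = 0.10,
    ground_noise_sd: float = 0.01,
) -> pd.DataFrame:
    """LiDAR-like cloud: ground grid plus canopy points per plant.

    Returns a DataFrame with columns ``x, y, z, label`` (``ground`` /
    ``canopy`` truth labels) plus ``plot_id`` and ``row_index`` for canopy
    points.  Plant height and point count scale with the row's latent trait
    mean and with :func:`growth_scale`; ``flight_gdd=0`` yields ground only.
    Canopy points are clipped laterally into the row's nominal strip.
    """
    c = trial.config
    rng = rng_for(c.rng_seed if seed is None else seed, "cloud", round(flight_gdd, 3))
    g = growth_scale(flight_gdd)

    x_max = trial.plots["x0"].max() + c.plot_pitch_x
    y_max = trial.plots["y0"].max() + c.plot_pitch_y
    margin = 0.5
    gx = np.arange(-margin, x_max + margin, ground_spacing_m)
    gy = np.arange(-margin, y_max + margin, ground_spacing_m)
    gxx, gyy = np.meshgrid(gx, gy)
    ground = pd.DataFrame(
        {
            "x": gxx.ravel(),
            "y": gyy.ravel(),
            "z": rng.normal(0.0, ground_noise_sd, size=gxx.size),
            "label": "ground",
            "plot_id": "",
            "row_index": 0,
        }
    )
    if g <= 0.0:
        return ground

    latent = trial.truth.set_index(["plot_id", "row_index"])["latent"]
    plants = trial.plants
    lat = latent.loc[
        pd.MultiIndex.from_frame(plants[["plot_id", "row_index"]])
    ].to_numpy()
    lat = np.clip(lat, 0.05, None)
    plant_factor = 1.0 + np.where(plants["end_zone"].to_numpy(), c.alley_end_shift, 0.0)
    plant_factor *= np.clip(rng.normal(1.0, 0.05, size=len(plants)), 0.7, 1.3)

    heights = REF_HEIGHT_M * g * lat * plant_factor
    n_pts = np.maximum(
        0, np.round(REF_POINTS_PER_PLANT * g * lat * plant_factor).astype(int)
    )

    half_strip = c.row_spacing_m / 2.0 - 1e-6
    px = np.repeat(plants["x"].to_numpy(), n_pts)
    py = np.repeat(plants["y"].to_numpy(), n_pts)
    ph = np.repeat(heights, n_pts)
    pid = np.repeat(plants["plot_id"].to_numpy(), n_pts)
    prow = np.repeat(plants["row_index"].to_numpy(), n_pts)
    total = int(n_pts.sum())
    if total == 0:
        return ground

    # row center line per plant, for clipping lateral spread into the strip
    plot_y0 = trial.plots.set_index("plot_id")["y0"]
    row_center = plot_y0.loc[pid].to_numpy() + (prow - 0.5) * c.row_spacing_m

    xs = px + rng.normal(0.0, 0.06, size=total)
    ys = row_center + np.clip(
        (py - row_center) + rng.normal(0.0, 0.08, size=total), -half_strip, half_strip
    )
    # vertical profile: denser toward the top of the canopy, p95 near height
    zs = ph * (0.15 + 0.85 * rng.random(total) ** 0.6)
    canopy = pd.DataFrame(
        {"x": xs, "y": ys, "z": zs, "label": "canopy", "plot_id": pid, "row_index": prow}
    )
    return pd.concat([ground, canopy], ignore_index=True)


def save_point_cloud(cloud: pd.DataFrame, path: str | Path) -> None:
    """Write a cloud as plain XYZ+label CSV."""
    cloud.to_csv(path, index=False)


def load_point_cloud(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def vegetation_spectrum(latent: np.ndarray) -> np.ndarray:
    """Per-row vegetation reflectance; NIR plateau scales with latent vigor.

    Returns an array of shape ``latent.shape + (n_bands,)``; the red/NIR
    contrast grows with the latent value, soil stays fixed.
    """
    latent = np.asarray(latent, dtype=float)
    spec = np.broadcast_to(VEG_SPECTRUM, latent.shape + VEG_SPECTRUM.shape).copy()
    scale = np.clip(0.6 + 0.4 * latent, 0.2, 1.9)
    spec[..., _NIR_MASK] = spec[..., _NIR_MASK] * scale[..., None]
    return np.clip(spec, 0.005, 0.95)


def render_rasters(
    trial: FieldTrial,
    flight_gdd: float,
    seed: int | None = None,
    rgb_gsd: float = 0.01,
    hs_gsd: float = 0.04,
) -> tuple[Raster, Raster]:
    """Render (RGB, hyperspectral) rasters for one flight.

    Vegetation is painted as per-plant discs whose radius grows with
    :func:`growth_scale` and the row's latent mean.  RGB vegetation pixels get
    HSV colors inside the default vegetation thresholds (hue 95-145 deg,
    saturation/value well above threshold) and soil pixels colors outside them;
    hyperspectral pixels get the soil template or the row's vegetation
    spectrum.  Both rasters share the field-local world frame.
    """
    c = trial.config
    rng = rng_for(c.rng_seed if seed is None else seed, "raster", round(flight_gdd, 3))
    g = growth_scale(flight_gdd)

    x_max = float(trial.plots["x0"].max() + c.plot_pitch_x)
    y_max = float(trial.plots["y0"].max() + c.plot_pitch_y)

    latent = trial.truth.set_index(["plot_id", "row_index"])["latent"]
    plants = trial.plants
    lat = latent.loc[
        pd.MultiIndex.from_frame(plants[["plot_id", "row_index"]])
    ].to_numpy()
    lat = np.clip(lat, 0.05, None)
    radii = REF_RADIUS_M * g * np.sqrt(lat) * (
        1.0 + np.where(plants["end_zone"].to_numpy(), c.alley_end_shift, 0.0)
    )

    def paint(gsd: float) -> tuple[np.ndarray, np.ndarray]:
        h = int(round(y_max / gsd))
        w = int(round(x_max / gsd))
        veg = np.zeros((h, w), dtype=bool)
        vig = np.zeros((h, w), dtype=np.float32)
        if g > 0:
            px = plants["x"].to_numpy() / gsd
            py = plants["y"].to_numpy() / gsd
            pr = radii / gsd
            for xc, yc, r, lv in zip(px, py, pr, lat):
                if r <= 0:
                    continue
                c0 = max(0, int(xc - r))
                c1 = min(w, int(xc + r) + 2)
                r0 = max(0, int(yc - r))
                r1 = min(h, int(yc + r) + 2)
                if c1 <= c0 or r1 <= r0:
                    continue
                cols = np.arange(c0, c1) + 0.5
                rws = np.arange(r0, r1) + 0.5
                dist2 = (cols[None, :] - xc) ** 2 + (rws[:, None] - yc) ** 2
                disc = dist2 <= r * r
                veg[r0:r1, c0:c1] |= disc
                patch = vig[r0:r1, c0:c1]
                patch[disc] = np.maximum(patch[disc], lv)
        return veg, vig

    # RGB: HSV inside/outside the vegetation thresholds, then to uint8 RGB
    veg_rgb, _ = paint(rgb_gsd)
    h_, w_ = veg_rgb.shape
    hsv = np.empty((h_, w_, 3), dtype=np.float32)
    hsv[..., 0] = np.where(
        veg_rgb,
        rng.uniform(95 / 360, 145 / 360, size=veg_rgb.shape),
        rng.uniform(20 / 360, 40 / 360, size=veg_rgb.shape),
    )
    hsv[..., 1] = np.where(veg_rgb, rng.uniform(0.45, 0.8, size=veg_rgb.shape), rng.uniform(0.2, 0.4, size=veg_rgb.shape))
    hsv[..., 2] = np.where(veg_rgb, rng.uniform(0.3, 0.6, size=veg_rgb.shape), rng.uniform(0.35, 0.65, size=veg_rgb.shape))
    rgb = Raster(
        data=(hsv_to_rgb(hsv) * 255).astype(np.uint8),
        x_origin=0.0,
        y_origin=0.0,
        gsd=rgb_gsd,
        meta={"flight_gdd": flight_gdd, "kind": "rgb"},
    )

    # Hyperspectral: soil template vs per-pixel vegetation spectrum
    veg_hs, vig_hs = paint(hs_gsd)
    hh, ww = veg_hs.shape
    cube = np.broadcast_to(
        SOIL_SPECTRUM.astype(np.float32), (hh, ww, len(WAVELENGTHS_NM))
    ).copy()
    if veg_hs.any():
        cube[veg_hs] = vegetation_spectrum(vig_hs[veg_hs]).astype(np.float32)
    cube += rng.normal(0.0, 0.004, size=cube.shape).astype(np.float32)
    cube = np.clip(cube, 0.001, 1.0)
    hyper = Raster(
        data=cube,
        x_origin=0.0,
        y_origin=0.0,
        gsd=hs_gsd,
        wavelengths_nm=WAVELENGTHS_NM.copy(),
        meta={"flight_gdd": flight_gdd, "kind": "hyperspectral"},
    )
    return rgb, hyper


# ---------------------------------------------------------------------------
# Direct trait-observation simulation (for large replicated studies)

def simulate_trait_observations(
    trial: FieldTrial,
    flight_gdds: Sequence[float],
    selections: Sequence[str] = tuple(ROW_SELECTIONS),
    trims: Sequence[bool] = (False, True),
    measurement_sd: float = 0.05,
    trait: str = "canopy_vigor",
    year: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trait observations per (plot, selection, trim, flight) from latent truth.

    Models the measurement chain without rendering: a selection's value is the
    mean of its member rows' latent means plus the mean of independent per-row
    measurement errors (so pooling more rows shrinks the error sd by
    ``1/sqrt(n_rows)``), the whole observation scaled by :func:`growth_scale`.
    Errors are drawn independently per (plot, selection, trim, flight) cell.
    Trimmed and untrimmed variants differ only through that independent noise —
    trimming introduces no systematic shift, matching a grid anchored on
    early-season plant extent.

    Returns a long DataFrame with columns ``plot_id, genotype, rep,
    subpopulation, year, flight_id, gdd, selection, trimmed, trait, value``.
    """
    c = trial.config
    rng = rng_for(c.rng_seed if seed is None else seed, "traits", year)
    truth = trial.truth.merge(
        trial.plots[["plot_id", "genotype", "rep", "subpopulation"]], on="plot_id"
    )
    frames = []
    meta = trial.plots.set_index("plot_id")
    for fi, gdd in enumerate(flight_gdds):
        gscale = growth_scale(gdd)
        for trimmed in trims:
            for sel in selections:
                members = list(ROW_SELECTIONS[sel])
                latent_mean = (
                    truth[truth["row_index"].isin(members)]
                    .groupby("plot_id")["latent"]
                    .mean()
                )
                err_sd = measurement_sd / math.sqrt(len(members))
                vals = gscale * (
                    latent_mean
                    + rng.normal(0.0, err_sd, size=len(latent_mean))
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "plot_id": vals.index,
                            "genotype": meta.loc[vals.index, "genotype"].to_numpy(),
                            "rep": meta.loc[vals.index, "rep"].to_numpy(),
                            "subpopulation": meta.loc[
                                vals.index, "subpopulation"
                            ].to_numpy(),
                            "year": year,
                            "flight_id": f"F{fi + 1:02d}",
                            "gdd": gdd,
                            "selection": sel,
                            "trimmed": trimmed,
                            "trait": trait,
                            "value": vals.to_numpy(),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
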