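"""Trait extraction against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from rowseg import Raster, RowSegmentBox
from rowseg.errors import DataError
from rowseg.plot_geometry import select_rows
from rowseg.synthetic_field import WAVELENGTHS_NM
from rowseg.trait_extraction import (
    canopy_cover_lidar,
    canopy_cover_rgb,
    classify_ground,
    height_p95,
    mask_ground_hyperspectral,
    plot_volume,
    points_in_boxes,
    vegetation_index,
)

BOX = RowSegmentBox("P", 1, 0.0, 1.0, 0.0, 1.0)


def _cloud(z, label="canopy", x=None, y=None):
    n = len(z)
    return pd.DataFrame(
        {
            "x": np.full(n, 0.5) if x is None else x,
            "y": np.full(n, 0.5) if y is None else y,
            "z": z,
            "label": [label] * n if isinstance(label, str) else label,
        }
    )


# -- CC10 -------------------------------------------------------------------

def test_cc10_hand_oracle_mixed_ground_canopy():
    # 10 ground at z=0, 10 canopy at 1.0..1.9: threshold = 10th pct = 1.09,
    # 9 of 20 points are strictly above it.
    z = np.concatenate([np.zeros(10), 1.0 + 0.1 * np.arange(10)])
    labels = ["ground"] * 10 + ["canopy"] * 10
    pts = _cloud(z, label=labels)
    zstar = np.percentile(z[10:], 10)
    expected = (z > zstar).sum() / 20
    assert expected == pytest.approx(0.45)
    assert canopy_cover_lidar(pts, [BOX]) == pytest.approx(expected)


def test_cc10_single_population_reading_is_090():
    pts = _cloud(np.linspace(0.1, 2.0, 100))
    assert canopy_cover_lidar(pts, [BOX], population="all") == pytest.approx(0.9, abs=0.02)


def test_cc10_missing_when_no_nonground():
    pts = _cloud(np.zeros(5), label="ground")
    assert np.isnan(canopy_cover_lidar(pts, [BOX]))


# -- Height95 ---------------------------------------------------------------

def test_height_p95_linear_interpolation_oracle():
    pts = _cloud(np.array([1.0, 2.0]))
    assert height_p95(pts, [BOX]) == pytest.approx(1.95)


def test_height_p95_ignores_ground_points():
    canopy = _cloud(np.full(10, 1.3))
    mixed = pd.concat([canopy, _cloud(np.zeros(50), label="ground")], ignore_index=True)
    assert height_p95(mixed, [BOX]) == pytest.approx(1.3)
    assert height_p95(canopy, [BOX]) == pytest.approx(1.3)


# -- Plot volume ------------------------------------------------------------

def test_plot_volume_single_cell_hand_oracle():
    box = RowSegmentBox("P", 1, 0.0, 0.08, 0.0, 0.08)
    pts = _cloud(np.array([0.5, 1.5]), x=np.array([0.04, 0.04]), y=np.array([0.04, 0.04]))
    # h = (p95 + min)/2 = (1.45 + 0.5)/2 = 0.975; area = 0.0064
    assert plot_volume(pts, [box]) == pytest.approx(0.975 * 0.0064)


def test_plot_volume_zero_without_nonground():
    assert plot_volume(_cloud(np.zeros(4), label="ground"), [BOX]) == 0.0


def test_plot_volume_linear_in_height(rng):
    pts = _cloud(rng.uniform(0.2, 2.0, 200), x=rng.uniform(0, 1, 200), y=rng.uniform(0, 1, 200))
    doubled = pts.assign(z=2 * pts["z"])
    assert plot_volume(doubled, [BOX]) == pytest.approx(2 * plot_volume(pts, [BOX]))


def brute_volume(points, box, cell=0.08):
    """Per-point re-binning oracle, plain loops."""
    import math

    nx = math.ceil(box.length / cell - 1e-9)
    ny = math.ceil(box.width / cell - 1e-9)
    cells = {}
    for _, p in points.iterrows():
        if p["label"] == "ground":
            continue
        if not (box.x_min <= p.x < box.x_max and box.y_min <= p.y < box.y_max):
            continue
        i = min(int((p.x - box.x_min) / cell), nx - 1)
        j = min(int((p.y - box.y_min) / cell), ny - 1)
        cells.setdefault((i, j), []).append(p.z)
    out = 0.0
    for (i, j), zz in cells.items():
        h = (np.percentile(zz, 95) + min(zz)) / 2
        out += h * min(cell, box.length - i * cell) * min(cell, box.width - j * cell)
    return out


def test_plot_volume_matches_brute_force_on_random_cloud(rng):
    box = RowSegmentBox("P", 1, 0.0, 1.3, 0.0, 0.76)  # clipped edge cells
    n = 800
    pts = pd.DataFrame(
        {
            "x": rng.uniform(-0.1, 1.4, n),
            "y": rng.uniform(-0.1, 0.9, n),
            "z": rng.uniform(0.0, 2.5, n),
            "label": rng.choice(["ground", "canopy"], n),
        }
    )
    assert plot_volume(pts, [box]) == pytest.approx(brute_volume(pts, box), rel=1e-9)


# -- Ground classification --------------------------------------------------

def test_classify_ground_recovers_truth_labels(tiny_trial):
    from rowseg.synthetic_field import render_point_cloud

    cloud = render_point_cloud(tiny_trial, 900.0, ground_spacing_m=0.25)
    pred = classify_ground(cloud, h0=0.10)
    tall = cloud[(cloud.label == "ground") | (cloud.z > 0.3)]
    acc = (pred[tall.index] == tall["label"]).mean()
    assert acc >= 0.99


def test_classify_ground_flat_field_is_all_ground():
    pts = _cloud(np.zeros(20), x=np.linspace(0, 1, 20), y=np.linspace(0, 1, 20))
    assert (classify_ground(pts) == "ground").all()


# -- RGB canopy cover -------------------------------------------------------

def _rgb_raster(mask, gsd=0.01):
    h, w = mask.shape
    data = np.zeros((h, w, 3))
    data[mask] = [0.2, 0.7, 0.2]     # green: hue 120, sat ~0.71, val 0.7
    data[~mask] = [0.5, 0.4, 0.3]    # brown: hue 30
    return Raster(data=data, x_origin=0.0, y_origin=0.0, gsd=gsd)


def test_canopy_cover_known_painted_fraction(rng):
    mask = rng.random((100, 100)) < 0.37
    raster = _rgb_raster(mask)
    cc = canopy_cover_rgb(raster, [BOX])
    assert cc == pytest.approx(mask.mean(), abs=1e-9)


@pytest.mark.parametrize("veg,expected", [(True, 1.0), (False, 0.0)])
def test_canopy_cover_pure_patches(veg, expected):
    mask = np.full((50, 50), veg)
    assert canopy_cover_rgb(_rgb_raster(mask), [BOX]) == expected


def test_canopy_cover_errors_outside_raster():
    raster = _rgb_raster(np.ones((10, 10), dtype=bool))
    far = RowSegmentBox("P", 1, 50.0, 51.0, 50.0, 51.0)
    with pytest.raises(DataError):
        canopy_cover_rgb(raster, [far])


# -- Hyperspectral ----------------------------------------------------------

def _uniform_hyper(values: dict, shape=(10, 10)):
    data = np.zeros(shape + (len(WAVELENGTHS_NM),))
    for wl, v in values.items():
        data[..., list(WAVELENGTHS_NM).index(wl)] = v
    return Raster(data=data, x_origin=0.0, y_origin=0.0, gsd=0.1,
                  wavelengths_nm=WAVELENGTHS_NM)


@pytest.mark.parametrize(
    "values,index,expected",
    [
        ({750: 0.6, 705: 0.2}, "NDVI", 0.5),
        ({680: 0.1, 500: 0.05, 750: 0.5}, "PSRI", 0.1),
        ({800: 0.3, 670: 0.3}, "OSAVI", 0.0),
        ({695: 0.4, 420: 0.2}, "Carte1", 2.0),
        ({740: 0.45, 720: 0.15}, "VOG1", 3.0),
        ({531: 0.3, 570: 0.1}, "PRI", 0.5),
    ],
)
def test_index_formulas_on_uniform_pixels(values, index, expected):
    raster = _uniform_hyper({wl: 0.01 for wl in WAVELENGTHS_NM} | values)
    mask = np.ones(raster.data.shape[:2], dtype=bool)
    assert vegetation_index(raster, [BOX], index, mask=mask) == pytest.approx(expected)


def test_soil_is_fully_masked_out(tiny_rasters, tiny_boxes, tiny_trial):
    _, hyper = tiny_rasters
    pid = tiny_trial.plots["plot_id"].iloc[0]
    boxes = select_rows(pid, "RS1234", tiny_boxes)
    mask = mask_ground_hyperspectral(hyper, boxes)
    ndvi_img = (hyper.band(750) - hyper.band(705)) / (hyper.band(750) + hyper.band(705))
    assert (ndvi_img[mask] > 0.5).all()


def test_threshold_minus_one_keeps_all_ndvi_pixels(tiny_rasters, tiny_boxes):
    _, hyper = tiny_rasters
    box = tiny_boxes[0]
    mask = mask_ground_hyperspectral(hyper, [box], threshold=-1.0)
    rs, cs = hyper.window(box)
    assert mask[rs, cs].all()


def test_missing_band_is_reported_by_wavelength():
    sub = WAVELENGTHS_NM[WAVELENGTHS_NM != 750.0]
    raster = Raster(
        data=np.zeros((5, 5, len(sub))), x_origin=0, y_origin=0, gsd=0.1,
        wavelengths_nm=sub,
    )
    with pytest.raises(DataError, match="750"):
        vegetation_index(raster, [BOX], "NDVI", mask=np.ones((5, 5), bool))


def test_empty_vegetation_mask_flags_missing():
    raster = _uniform_hyper({wl: 0.2 for wl in WAVELENGTHS_NM})
    assert np.isnan(vegetation_index(raster, [BOX], "NDVI"))


# -- Invariances ------------------------------------------------------------

def test_traits_invariant_to_point_order_and_translation(rng):
    n = 500
    pts = pd.DataFrame(
        {
            "x": rng.uniform(0, 1, n),
            "y": rng.uniform(0, 1, n),
            "z": rng.uniform(0, 2, n),
            "label": rng.choice(["ground", "canopy"], n),
        }
    )
    shuffled = pts.sample(frac=1, random_state=0).reset_index(drop=True)
    shifted = pts.assign(x=pts.x + 100, y=pts.y - 55)
    sbox = RowSegmentBox("P", 1, 100.0, 101.0, -55.0, -54.0)
    for f in (height_p95, canopy_cover_lidar, plot_volume):
        assert f(pts, [BOX]) == pytest.approx(f(shuffled, [BOX]), rel=1e-12)
        assert f(pts, [BOX]) == pytest.approx(f(shifted, [sbox]), rel=1e-9)


def test_pooled_rs1234_equals_weighted_row_combination(tiny_trial, tiny_boxes, tiny_cloud):
    pid = tiny_trial.plots["plot_id"].iloc[0]
    full = select_rows(pid, "RS1234", tiny_boxes)
    pooled = canopy_cover_lidar(tiny_cloud, full)
    # weighted combination: counts above the POOLED threshold per row
    sub = tiny_cloud[points_in_boxes(tiny_cloud, full)]
    zstar = np.percentile(sub[sub.label != "ground"]["z"], 10)
    num = tot = 0
    for b in full:
        row_pts = tiny_cloud[points_in_boxes(tiny_cloud, [b])]
        num += (row_pts["z"] > zstar).sum()
        tot += len(row_pts)
    assert pooled == pytest.approx(num / tot)


def test_border_shift_recovered_from_height_traits():
    from rowseg import TrialConfig, simulate_trial
    from rowseg.plot_geometry import build_grid
    from rowseg.synthetic_field import render_point_cloud

    cfg = TrialConfig(n_genotypes=16, border_effect_mean_shift=0.25,
                      border_extra_sd=0.0, residual_variance=0.0, rng_seed=21)
    trial = simulate_trial(cfg)
    cloud = render_point_cloud(trial, 800.0)
    boxes = build_grid(trial.plants)
    h14, h23 = [], []
    for pid in trial.plots["plot_id"]:
        h14.append(height_p95(cloud, select_rows(pid, "RS14", boxes)))
        h23.append(height_p95(cloud, select_rows(pid, "RS23", boxes)))
    # relative height excess should track the configured latent shift (~25%)
    excess = np.mean(h14) / np.mean(h23) - 1
    assert excess == pytest.approx(0.25, abs=0.10)
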