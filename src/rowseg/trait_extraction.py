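"""Geometric and spectral trait extraction for row-segment boxes.

All operations take a set of :class:`~rowseg.plot_geometry.RowSegmentBox` and
pool the points/pixels of the selected boxes before computing the statistic
(rather than averaging per-row values); percentiles use linear interpolation
between order statistics.  A trait that cannot be computed (no vegetation, no
nonground points) returns NaN and logs, so sweeps continue past empty cells.

Traits
------
CC          RGB canopy cover: vegetation-pixel fraction by HSV thresholding
CC10        LiDAR canopy cover: points above the 10th percentile of nonground
            heights over all points in the boxes
Height95    95th percentile of nonground point heights (m)
PlotVolume  8 cm grid-cell volume, cell height = (p95 + min)/2 of nonground z
indices     Carte1, GNDVI, mRENDVI, NDVI, OSAVI, PRI, PSRI, SR800680,
            SR700670, VOG1 — mean over vegetation pixels
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import rgb_to_hsv

from .errors import DataError
from .plot_geometry import RowSegmentBox
from .raster import Raster

log = logging.getLogger(__name__)

GROUND = "ground"
CANOPY = "canopy"


# ---------------------------------------------------------------------------
# Point helpers

def points_in_boxes(points: pd.DataFrame, boxes: Iterable[RowSegmentBox]) -> np.ndarray:
    """Boolean mask of points inside any of the boxes ([min, max) membership)."""
    x = points["x"].to_numpy()
    y = points["y"].to_numpy()
    mask = np.zeros(len(points), dtype=bool)
    for b in boxes:
        if b.missing:
            continue
        mask |= b.contains(x, y)
    return mask


def classify_ground(
    points: pd.DataFrame, cell_m: float = 0.5, h0: float = 0.10
) -> np.ndarray:
    """Label points ground/nonground by a local minimum-elevation rule.

    The field is tiled with ``cell_m`` cells; within each cell the minimum z
    estimates the ground elevation, and points within ``h0`` of it are ground.
    Returns an array of ``"ground"`` / ``"canopy"`` labels.  Synthetic truth
    labels, when present, may be used directly instead of calling this.
    """
    if len(points) == 0:
        raise DataError("classify_ground: empty point set")
    x = points["x"].to_numpy()
    y = points["y"].to_numpy()
    z = points["z"].to_numpy()
    ci = np.floor((x - x.min()) / cell_m).astype(np.int64)
    cj = np.floor((y - y.min()) / cell_m).astype(np.int64)
    key = ci * (cj.max() + 1) + cj
    ground_z = pd.Series(z).groupby(key).transform("min").to_numpy()
    return np.where(z <= ground_z + h0, GROUND, CANOPY)


def _split_points(points: pd.DataFrame, boxes: Iterable[RowSegmentBox]):
    boxes = [b for b in boxes if not b.missing]
    mask = points_in_boxes(points, boxes)
    sub = points.loc[mask]
    if "label" not in sub.columns:
        raise DataError("points need a 'label' column (run classify_ground)")
    nonground = sub.loc[sub["label"] != GROUND]
    return sub, nonground


# ---------------------------------------------------------------------------
# RGB canopy cover

@dataclass(frozen=True)
class HsvThresholds:
    """Vegetation classification window in HSV space.

    Hue is in degrees; a pixel is vegetation when ``hue_min <= hue <= hue_max``
    and saturation and value are strictly above their minima (ties break
    toward non-vegetation).
    """

    hue_min_deg: float = 60.0
    hue_max_deg: float = 180.0
    sat_min: float = 0.15
    val_min: float = 0.10


def classify_vegetation_rgb(rgb: np.ndarray, thresholds: HsvThresholds | None = None) -> np.ndarray:
    """Boolean vegetation mask for an (H, W, 3) RGB array (uint8 or float)."""
    thresholds = thresholds or HsvThresholds()
    arr = np.asarray(rgb, dtype=float)
    if arr.max() > 1.0:
        arr = arr / 255.0
    hsv = rgb_to_hsv(arr)
    hue = hsv[..., 0] * 360.0
    return (
        (hue >= thresholds.hue_min_deg)
        & (hue <= thresholds.hue_max_deg)
        & (hsv[..., 1] > thresholds.sat_min)
        & (hsv[..., 2] > thresholds.val_min)
    )


def canopy_cover_rgb(
    raster: Raster,
    boxes: Iterable[RowSegmentBox],
    thresholds: HsvThresholds | None = None,
) -> float:
    """Vegetation-pixel fraction over all pixels inside the boxes (pooled)."""
    boxes = [b for b in boxes if not b.missing]
    total = 0
    veg = 0
    for b in boxes:
        rs, cs = raster.window(b)
        patch = raster.data[rs, cs]
        if patch.size == 0:
            continue
        m = classify_vegetation_rgb(patch, thresholds)
        total += m.size
        veg += int(m.sum())
    if total == 0:
        raise DataError("canopy_cover_rgb: no pixels inside the supplied boxes")
    return veg / total


# ---------------------------------------------------------------------------
# LiDAR traits

def canopy_cover_lidar(
    points: pd.DataFrame,
    boxes: Iterable[RowSegmentBox],
    percentile: float = 10.0,
    population: str = "nonground",
) -> float:
    """CC10: fraction of all in-box points above a low height threshold.

    The threshold is the ``percentile``-th percentile (linear interpolation) of
    nonground heights by default; ``population="all"`` reproduces the literal
    single-population reading, which is definitionally ~0.9 for distinct
    heights.  The denominator always pools ground and nonground points.
    """
    sub, nonground = _split_points(points, boxes)
    if len(sub) == 0:
        raise DataError("canopy_cover_lidar: no points inside boxes")
    pop = sub if population == "all" else nonground
    if len(pop) == 0:
        log.warning("canopy_cover_lidar: no nonground points; trait missing")
        return float("nan")
    z_star = float(np.percentile(pop["z"].to_numpy(), percentile))
    return float((sub["z"].to_numpy() > z_star).sum() / len(sub))


def height_p95(
    points: pd.DataFrame, boxes: Iterable[RowSegmentBox], q: float = 95.0
) -> float:
    """95th percentile of nonground point heights inside the boxes (m)."""
    _, nonground = _split_points(points, boxes)
    if len(nonground) == 0:
        log.warning("height_p95: no nonground points; trait missing")
        return float("nan")
    return float(np.percentile(nonground["z"].to_numpy(), q))


def plot_volume(
    points: pd.DataFrame, boxes: Iterable[RowSegmentBox], cell_m: float = 0.08
) -> float:
    """Grid-cell canopy volume (m^3) pooled over the boxes.

    Each box is tiled from its (x_min, y_min) corner with ``cell_m`` square
    cells, edge cells clipped to the box.  A cell containing at least one
    nonground point contributes ``(p95(z) + min(z))/2 * clipped_area``; empty
    cells contribute nothing.
    """
    total = 0.0
    for b in boxes:
        if b.missing:
            continue
        mask = b.contains(points["x"].to_numpy(), points["y"].to_numpy())
        sub = points.loc[mask]
        sub = sub.loc[sub["label"] != GROUND] if "label" in sub.columns else sub
        if len(sub) == 0:
            continue
        nx = int(np.ceil(b.length / cell_m - 1e-9))
        ny = int(np.ceil(b.width / cell_m - 1e-9))
        ci = np.minimum(
            np.floor((sub["x"].to_numpy() - b.x_min) / cell_m).astype(int), nx - 1
        )
        cj = np.minimum(
            np.floor((sub["y"].to_numpy() - b.y_min) / cell_m).astype(int), ny - 1
        )
        z = sub["z"].to_numpy()
        df = pd.DataFrame({"ci": ci, "cj": cj, "z": z})
        for (i, j), grp in df.groupby(["ci", "cj"]):
            zz = grp["z"].to_numpy()
            h = (np.percentile(zz, 95.0) + zz.min()) / 2.0
            w_x = min(cell_m, b.length - i * cell_m)
            w_y = min(cell_m, b.width - j * cell_m)
            total += h * w_x * w_y
    return float(total)


# ---------------------------------------------------------------------------
# Hyperspectral indices

def _formula(name: str):
    """(required wavelengths, function of {wavelength: band array})."""
    F = {
        "Carte1": ((695, 420), lambda b: b[695] / b[420]),
        "GNDVI": ((750, 550), lambda b: (b[750] - b[550]) / (b[750] + b[550])),
        "mRENDVI": (
            (750, 705, 445),
            lambda b: (b[750] - b[705]) / (b[750] + b[705] - 2 * b[445]),
        ),
        "NDVI": ((750, 705), lambda b: (b[750] - b[705]) / (b[750] + b[705])),
        "OSAVI": (
            (800, 670),
            lambda b: (1 + 0.16) * (b[800] - b[670]) / (b[800] + b[670] + 0.16),
        ),
        "PRI": ((531, 570), lambda b: (b[531] - b[570]) / (b[531] + b[570])),
        "PSRI": ((680, 500, 750), lambda b: (b[680] - b[500]) / b[750]),
        "SR800680": ((800, 680), lambda b: b[800] / b[680]),
        "SR700670": ((700, 670), lambda b: b[700] / b[670]),
        "VOG1": ((740, 720), lambda b: b[740] / b[720]),
    }
    if name not in F:
        raise DataError(f"unknown vegetation index {name!r}")
    return F[name]


VEGETATION_INDICES = (
    "Carte1",
    "GNDVI",
    "mRENDVI",
    "NDVI",
    "OSAVI",
    "PRI",
    "PSRI",
    "SR800680",
    "SR700670",
    "VOG1",
)


def _index_image(raster: Raster, name: str) -> np.ndarray:
    wavelengths, fn = _formula(name)
    bands = {wl: raster.band(wl).astype(float) for wl in wavelengths}
    with np.errstate(divide="ignore", invalid="ignore"):
        return fn(bands)


def mask_ground_hyperspectral(
    raster: Raster,
    boxes: Iterable[RowSegmentBox],
    index_name: str = "NDVI",
    threshold: float = 0.5,
) -> np.ndarray:
    """Full-raster boolean vegetation mask, restricted to pixels in boxes.

    A pixel is vegetation when its index value is strictly above ``threshold``
    (default NDVI > 0.5) and its center lies inside one of the boxes.
    """
    img = _index_image(raster, index_name)
    mask = np.zeros(img.shape, dtype=bool)
    for b in boxes:
        if b.missing:
            continue
        rs, cs = raster.window(b)
        mask[rs, cs] = True
    return mask & (img > threshold)


def vegetation_index(
    raster: Raster,
    boxes: Iterable[RowSegmentBox],
    index_name: str,
    mask: np.ndarray | None = None,
    mask_threshold: float = 0.5,
) -> float:
    """Mean index value over vegetation pixels inside the boxes.

    ``mask`` may be precomputed with :func:`mask_ground_hyperspectral`;
    otherwise an NDVI mask at ``mask_threshold`` is built.  Pixels whose
    formula divides by zero are excluded and logged; zero vegetation pixels
    yields NaN (trait flagged missing).
    """
    if mask is None:
        mask = mask_ground_hyperspectral(raster, boxes, threshold=mask_threshold)
    if not mask.any():
        log.warning("vegetation_index(%s): empty vegetation mask", index_name)
        return float("nan")
    img = _index_image(raster, index_name)
    vals = img[mask]
    bad = ~np.isfinite(vals)
    if bad.any():
        log.warning("vegetation_index(%s): %d non-finite pixels excluded", index_name, bad.sum())
        vals = vals[~bad]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Bulk extraction

GEOMETRIC_TRAITS = ("CC", "CC10", "Height95", "PlotVolume")


def extract_traits(
    boxes: Sequence[RowSegmentBox],
    points: pd.DataFrame | None = None,
    rgb: Raster | None = None,
    hyper: Raster | None = None,
    traits: Sequence[str] = GEOMETRIC_TRAITS + ("NDVI",),
    hsv_thresholds: HsvThresholds | None = None,
    mask_threshold: float = 0.5,
) -> dict[str, float]:
    """Compute the requested traits for one pooled set of boxes."""
    out: dict[str, float] = {}
    hs_mask = None
    for t in traits:
        if t == "CC":
            if rgb is None:
                raise DataError("trait CC needs an RGB raster")
            out[t] = canopy_cover_rgb(rgb, boxes, hsv_thresholds)
        elif t == "CC10":
            if points is None:
                raise DataError("trait CC10 needs a point cloud")
            out[t] = canopy_cover_lidar(points, boxes)
        elif t == "Height95":
            if points is None:
                raise DataError("trait Height95 needs a point cloud")
            out[t] = height_p95(points, boxes)
        elif t == "PlotVolume":
            if points is None:
                raise DataError("trait PlotVolume needs a point cloud")
            out[t] = plot_volume(points, boxes)
        elif t in VEGETATION_INDICES:
            if hyper is None:
                raise DataError(f"trait {t} needs a hyperspectral raster")
            if hs_mask is None:
                hs_mask = mask_ground_hyperspectral(hyper, boxes, threshold=mask_threshold)
            out[t] = vegetation_index(hyper, boxes, t, mask=hs_mask)
        else:
            raise DataError(f"unknown trait {t!r}")
    return out
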