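"""Minimal georeferenced raster container.

A :class:`Raster` is a numpy array plus an affine north-up world transform
(origin + square ground sampling distance) and, for hyperspectral data, the
per-band wavelengths.  Rasters round-trip to a plain TIFF (via ``tifffile``)
with a JSON sidecar holding the transform and wavelengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import DataError
from .plot_geometry import RowSegmentBox


@dataclass
class Raster:
    """Image data with a world transform.

    ``data`` has shape (H, W) or (H, W, C); pixel (row, col) covers the world
    rectangle ``[x0 + col*gsd, x0 + (col+1)*gsd) x [y0 + row*gsd, y0 + (row+1)*gsd)``
    and its center sits at ``(x0 + (col+0.5)*gsd, y0 + (row+0.5)*gsd)``.
    """

    data: np.ndarray
    x_origin: float
    y_origin: float
    gsd: float
    wavelengths_nm: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gsd <= 0:
            raise DataError("raster gsd must be > 0")
        if self.wavelengths_nm is not None:
            self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
            if self.data.ndim != 3 or self.data.shape[2] != len(self.wavelengths_nm):
                raise DataError("band count does not match wavelengths")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World x of every column center, world y of every row center."""
        h, w = self.data.shape[:2]
        xs = self.x_origin + (np.arange(w) + 0.5) * self.gsd
        ys = self.y_origin + (np.arange(h) + 0.5) * self.gsd
        return xs, ys

    def window(self, box: RowSegmentBox) -> tuple[slice, slice]:
        """Row/col slices of pixels whose centers fall inside the box ([min, max))."""
        xs, ys = self.pixel_centers()
        cols = np.flatnonzero((xs >= box.x_min) & (xs < box.x_max))
        rows = np.flatnonzero((ys >= box.y_min) & (ys < box.y_max))
        if len(cols) == 0 or len(rows) == 0:
            return slice(0, 0), slice(0, 0)
        return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)

    def band(self, wavelength_nm: float, tol_nm: float = 3.0) -> np.ndarray:
        """Band whose wavelength is nearest the request, within ``tol_nm``."""
        if self.wavelengths_nm is None:
            raise DataError("raster has no wavelength information")
        idx = int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))
        if abs(self.wavelengths_nm[idx] - wavelength_nm) > tol_nm:
            raise DataError(f"no band within {tol_nm} nm of {wavelength_nm} nm")
        return self.data[:, :, idx]

    # -- I/O -----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.data)
        sidecar = {
            "x_origin": self.x_origin,
            "y_origin": self.y_origin,
            "gsd": self.gsd,
            "wavelengths_nm": None
            if self.wavelengths_nm is None
            else list(map(float, self.wavelengths_nm)),
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "Raster":
        path = Path(path)
        data = tifffile.imread(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        wl = sidecar.get("wavelengths_nm")
        return cls(
            data=data,
            x_origin=sidecar["x_origin"],
            y_origin=sidecar["y_origin"],
            gsd=sidecar["gsd"],
            wavelengths_nm=None if wl is None else np.asarray(wl),
            meta=sidecar.get("meta", {}),
        )
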