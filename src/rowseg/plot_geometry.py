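"""Row-segment geometry: the N x M grid of bounding boxes, end trimming, and
row-selection schemes.

Coordinates are field-local meters with x running along the rows.  Boxes are
axis-aligned rectangles treated as closed-open intervals ``[min, max)`` for
point/pixel membership, so adjacent boxes never double-count.  A box's
longitudinal extent spans from the proximal-most to the terminal-most emerged
plant of the row segment, so boxes of one field do not all share a size; its
lateral extent is the full row spacing centered on the row line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import GeometryError

#: The seven row-selection schemes for a four-row plot.
ROW_SELECTIONS: dict[str, tuple[int, ...]] = {
    "RS1234": (1, 2, 3, 4),
    "RS23": (2, 3),
    "RS14": (1, 4),
    "RS1": (1,),
    "RS2": (2,),
    "RS3": (3,),
    "RS4": (4,),
}

DEFAULT_TRIM_M = 0.40
MIN_BOX_LENGTH_M = 0.50


@dataclass(frozen=True)
class RowSegmentBox:
    """Axis-aligned rectangle enclosing one row segment of one plot.

    ``missing`` flags a row segment that could not be boxed (fewer than two
    emerged plants); such boxes are excluded downstream rather than raising.
    """

    plot_id: str
    row_index: int
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    trimmed: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            if not (self.x_min < self.x_max and self.y_min < self.y_max):
                raise GeometryError(
                    f"degenerate box for plot {self.plot_id} row {self.row_index}"
                )

    @property
    def length(self) -> float:
        return self.x_max - self.x_min

    @property
    def width(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.length * self.width

    def contains(self, x, y):
        """Closed-open membership test; works on scalars or arrays."""
        return (
            (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)
        )


def build_grid(
    plant_positions: pd.DataFrame,
    n_ranges: int | None = None,
    n_rows: int | None = None,
    row_spacing_m: float = 0.76,
) -> list[RowSegmentBox]:
    """Build one bounding box per (plot, row) from emerged-plant positions.

    Parameters
    ----------
    plant_positions
        Long table with columns ``plot_id``, ``row_index``, ``x``, ``y``; one
        row per plant.  The box for a row segment runs from the minimum to the
        maximum plant ``x`` and spans the full row spacing centered on the mean
        plant ``y`` (the row line).
    n_ranges, n_rows
        Optional expected grid shape; when given, the number of distinct plots
        must equal ``n_ranges * <plots per range>`` only loosely — they are used
        purely as a sanity check on the row count per plot.
    row_spacing_m
        Lateral box width.

    A row segment with fewer than two plants yields a ``missing``-flagged box.
    """
    required = {"plot_id", "row_index", "x", "y"}
    if not required.issubset(plant_positions.columns):
        raise GeometryError(f"plant_positions needs columns {sorted(required)}")
    boxes: list[RowSegmentBox] = []
    for (plot_id, row_index), grp in plant_positions.groupby(
        ["plot_id", "row_index"], sort=True
    ):
        if len(grp) < 2:
            boxes.append(
                RowSegmentBox(
                    plot_id=str(plot_id),
                    row_index=int(row_index),
                    x_min=0.0,
                    x_max=0.0,
                    y_min=0.0,
                    y_max=0.0,
                    missing=True,
                )
            )
            continue
        y_center = float(grp["y"].mean())
        boxes.append(
            RowSegmentBox(
                plot_id=str(plot_id),
                row_index=int(row_index),
                x_min=float(grp["x"].min()),
                x_max=float(grp["x"].max()),
                y_min=y_center - row_spacing_m / 2.0,
                y_max=y_center + row_spacing_m / 2.0,
            )
        )
    if n_rows is not None:
        per_plot = pd.Series([b.row_index for b in boxes]).groupby(
            pd.Series([b.plot_id for b in boxes])
        ).nunique()
        bad = per_plot[per_plot != n_rows]
        if len(bad):
            raise GeometryError(
                f"plot {bad.index[0]} has {bad.iloc[0]} rows, expected {n_rows}"
            )
    return boxes


def trim_box(
    box: RowSegmentBox,
    trim_m: float = DEFAULT_TRIM_M,
    min_length_m: float = MIN_BOX_LENGTH_M,
) -> RowSegmentBox:
    """Shrink the longitudinal extent by ``trim_m`` at each end.

    The lateral extent is unchanged and the result carries ``trimmed=True``.
    Raises :class:`GeometryError` naming the plot if the trimmed length would
    fall below ``min_length_m``.
    """
    if box.missing:
        return replace(box, trimmed=True)
    if trim_m < 0:
        raise GeometryError("trim_m must be >= 0")
    new_len = box.length - 2.0 * trim_m
    if new_len < min_length_m:
        raise GeometryError(
            f"trimming plot {box.plot_id} row {box.row_index} to {new_len:.2f} m "
            f"is below the {min_length_m:.2f} m minimum"
        )
    return replace(box, x_min=box.x_min + trim_m, x_max=box.x_max - trim_m, trimmed=True)


def select_rows(
    plot_id: str,
    selection: str | Sequence[int],
    boxes: Iterable[RowSegmentBox],
) -> list[RowSegmentBox]:
    """Return the member-row boxes of one plot for a selection scheme.

    ``selection`` is a scheme name (``RS1234`` ... ``RS4``) or an explicit
    sequence of row indices.  Raises :class:`GeometryError` naming the plot and
    row if a member row is absent or flagged missing.
    """
    if isinstance(selection, str):
        try:
            members = ROW_SELECTIONS[selection]
        except KeyError:
            raise GeometryError(f"unknown row selection {selection!r}") from None
    else:
        members = tuple(int(r) for r in selection)
    by_row: Mapping[int, RowSegmentBox] = {
        b.row_index: b for b in boxes if b.plot_id == plot_id
    }
    out = []
    for r in members:
        box = by_row.get(r)
        if box is None or box.missing:
            raise GeometryError(f"plot {plot_id}: row {r} missing, cannot select")
        out.append(box)
    return out


# ---------------------------------------------------------------------------
# GeoJSON round-trip

def boxes_to_geojson(boxes: Iterable[RowSegmentBox], path: str | Path | None = None):
    """Serialize boxes as a GeoJSON FeatureCollection of rectangles."""
    features = []
    for b in boxes:
        ring = [
            [b.x_min, b.y_min],
            [b.x_max, b.y_min],
            [b.x_max, b.y_max],
            [b.x_min, b.y_max],
            [b.x_min, b.y_min],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "plot_id": b.plot_id,
                    "row_index": b.row_index,
                    "trimmed": b.trimmed,
                    "missing": b.missing,
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection, indent=1))
    return collection


def boxes_from_geojson(source: str | Path | dict) -> list[RowSegmentBox]:
    """Inverse of :func:`boxes_to_geojson`."""
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    boxes = []
    for feat in source["features"]:
        props = feat["properties"]
        ring = feat["geometry"]["coordinates"][0]
        xs = [p[0] for p in ring]
        ys = [p[1] for p in ring]
        boxes.append(
            RowSegmentBox(
                plot_id=str(props["plot_id"]),
                row_index=int(props["row_index"]),
                x_min=min(xs),
                x_max=max(xs),
                y_min=min(ys),
                y_max=max(ys),
                trimmed=bool(props.get("trimmed", False)),
                missing=bool(props.get("missing", False)),
            )
        )
    return boxes
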