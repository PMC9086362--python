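"""Per-object geometry and the Feret-to-length conversion.

The maximum Feret diameter F of a segmented object is the largest distance
between any two points of its boundary; for a rod lying at an angle it is
the corner-to-corner diagonal of the rod. Given the known rod width W
(18 nm for TMV-like particles), the rod length is recovered as

    L = sqrt(F^2 - W^2).

Feret points are pixel *corners* (each pixel treated as a unit square), so
a single pixel has F = sqrt(2) px; this avoids the systematic one-pixel
underestimate of centre-to-centre distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage.measure import regionprops

from .io import px_to_nm
from .segmentation import LabelMap

#: Column order of the measurement CSV contract.
CSV_COLUMNS = [
    "source_id", "object_id", "area_nm2", "minor_axis_nm", "feret_max_nm",
    "length_nm", "centroid_row", "centroid_col", "truncated", "excluded",
]

_CORNERS = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)


@dataclass(frozen=True)
class MeasurementParams:
    rod_width_nm: float = 18.0

    def __post_init__(self) -> None:
        if not self.rod_width_nm > 0:
            raise ValueError("rod_width_nm must be > 0")


@dataclass
class RodMeasurement:
    """Geometry record for one segmented object.

    ``length_nm`` is NaN when the Feret diameter is smaller than the rod
    width (the object cannot be a rod of that width).
    """

    object_id: int
    area_nm2: float
    minor_axis_nm: float
    feret_max_nm: float
    length_nm: float
    centroid: tuple[float, float]
    truncated: bool = False
    excluded: bool = False
    source_id: str = ""

    @property
    def length_defined(self) -> bool:
        return math.isfinite(self.length_nm)


def feret_max(object_pixels: np.ndarray, pixel_size_nm: float) -> float:
    """Maximum Feret diameter (nm) over the corner points of an object.

    ``object_pixels`` is an (N, 2) array of (row, col) pixel coordinates.
    The maximum pairwise distance is attained on the convex hull of the
    4N pixel-corner points, so only hull vertices are compared.
    """
    coords = np.asarray(object_pixels, dtype=float)
    if coords.size == 0:
        raise ValueError("empty object")
    coords = coords.reshape(-1, 2)
    pts = (coords[:, None, :] + _CORNERS[None, :, :]).reshape(-1, 2)
    if len(pts) > 4:
        pts = pts[ConvexHull(pts).vertices]
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return math.sqrt(d2.max()) * pixel_size_nm


def rod_length(feret_max_nm: float, params: MeasurementParams | None = None) -> float:
    """Rod length L = sqrt(F^2 - W^2), or NaN when F < W."""
    if params is None:
        params = MeasurementParams()
    if feret_max_nm < 0:
        raise ValueError(f"negative Feret diameter {feret_max_nm}")
    w = params.rod_width_nm
    if feret_max_nm < w:
        return float("nan")
    return math.sqrt(feret_max_nm**2 - w**2)


def measure_all(
    label_map: LabelMap, params: MeasurementParams | None = None
) -> list[RodMeasurement]:
    """Measure every labelled object in a segmentation.

    The ``truncated`` flag is set when any object pixel lies on the image
    border; ``excluded`` starts False and is only ever set by the manual
    rogue-exclusion step.
    """
    if params is None:
        params = MeasurementParams()
    ps = label_map.pixel_size_nm
    nrows, ncols = label_map.labels.shape
    out: list[RodMeasurement] = []
    for prop in regionprops(label_map.labels):
        rmin, cmin, rmax, cmax = prop.bbox
        truncated = rmin == 0 or cmin == 0 or rmax == nrows or cmax == ncols
        f_nm = feret_max(prop.coords, ps)
        out.append(
            RodMeasurement(
                object_id=int(prop.label),
                area_nm2=px_to_nm(prop.area, ps, kind="area"),
                minor_axis_nm=px_to_nm(prop.axis_minor_length, ps, kind="length"),
                feret_max_nm=f_nm,
                length_nm=rod_length(f_nm, params),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                truncated=bool(truncated),
                excluded=False,
                source_id=label_map.source_id,
            )
        )
    return out


def measurements_to_frame(measurements: list[RodMeasurement]) -> pd.DataFrame:
    """Tabulate measurements in the canonical CSV column order."""
    rows = [
        {
            "source_id": m.source_id,
            "object_id": m.object_id,
            "area_nm2": m.area_nm2,
            "minor_axis_nm": m.minor_axis_nm,
            "feret_max_nm": m.feret_max_nm,
            "length_nm": m.length_nm,
            "centroid_row": m.centroid[0],
            "centroid_col": m.centroid[1],
            "truncated": m.truncated,
            "excluded": m.excluded,
        }
        for m in measurements
    ]
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return frame.sort_values(["source_id", "object_id"], kind="stable").reset_index(
        drop=True
    )


def write_measurements_csv(measurements: list[RodMeasurement] | pd.DataFrame, path) -> None:
    """Write the measurement table with fixed formatting (reproducible bytes)."""
    frame = (
        measurements
        if isinstance(measurements, pd.DataFrame)
        else measurements_to_frame(measurements)
    )
    frame.to_csv(path, index=False, float_format="%.4f")


def read_measurements_csv(path) -> list[RodMeasurement]:
    frame = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: measurement CSV missing columns {sorted(missing)}")
    return [
        RodMeasurement(
            object_id=int(row.object_id),
            area_nm2=float(row.area_nm2),
            minor_axis_nm=float(row.minor_axis_nm),
            feret_max_nm=float(row.feret_max_nm),
            length_nm=float(row.length_nm),
            centroid=(float(row.centroid_row), float(row.centroid_col)),
            truncated=bool(row.truncated),
            excluded=bool(row.excluded),
            source_id=str(row.source_id),
        )
        for row in frame.itertuples()
    ]
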