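"""Geometry extraction and pixel-to-physical calibration.

Areas are pixel counts (a region integral over the instance), perimeters
are polygonal lengths along the traced outer boundary (1 per axis step,
sqrt(2) per diagonal step).  Physical conversion keeps the tray-extent /
image-extent ratios as exact rationals internally — the familiar
0.0167 cm/px of a 25 cm tray imaged at 1500 px is a display rounding of
25/1500, and squaring the rounded value would bias areas by ~0.5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Calibration",
    "Contour",
    "LeafMeasurement",
    "make_calibration",
    "extract_contours",
    "pixel_area",
    "pixel_perimeter",
    "to_physical",
    "measure_instances",
    "write_measurements_csv",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class Calibration:
    """Physical <-> pixel conversion for a tray image.

    ``dx = Lx / width`` and ``dy = Ly / height`` are stored as exact
    :class:`fractions.Fraction` ratios; areas scale by ``dx*dy`` and
    lengths by ``dx``.
    """

    Lx: Fraction
    Ly: Fraction
    width: int
    height: int

    @property
    def dx(self) -> Fraction:
        return self.Lx / self.width

    @property
    def dy(self) -> Fraction:
        return self.Ly / self.height

    @property
    def dx_float(self) -> float:
        return float(self.dx)

    @property
    def dy_float(self) -> float:
        return float(self.dy)

    def __str__(self) -> str:  # 4-decimal display convention
        return (f"Calibration({float(self.Lx):g}cm x {float(self.Ly):g}cm @ "
                f"{self.width}x{self.height}px, dx={self.dx_float:.4f}, "
                f"dy={self.dy_float:.4f} cm/px)")


def make_calibration(Lx, Ly, width: int, height: int) -> Calibration:
    """Build a calibration from physical tray extent (cm) and image extent (px)."""
    if Lx <= 0 or Ly <= 0 or width <= 0 or height <= 0:
        raise ValueError("calibration extents must all be positive")
    return Calibration(Lx=Fraction(Lx), Ly=Fraction(Ly), width=int(width), height=int(height))


@dataclass(frozen=True)
class Contour:
    """Ordered ring of boundary pixel centers, (row, col), 8-connected."""

    points: Tuple[Tuple[int, int], ...]
    closed: bool = True

    def __post_init__(self):
        if len(self.points) < 1:
            raise ValueError("contour needs at least one point")


@dataclass(frozen=True)
class LeafMeasurement:
    """Per-instance geometry in pixels and physical units."""

    instance_id: int
    area_px: int
    perimeter_px: float
    area_cm2: float
    perimeter_cm: float
    centroid: Tuple[float, float]
    bbox: Tuple[int, int, int, int]  # half-open (row0, col0, row1, col1)


# Moore neighborhood in clockwise order starting West, for (row, col) rasters.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_moore(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Moore boundary tracing with Jacob's stopping criterion (clockwise).

    Terminates when the start pixel is re-entered and the same first move
    is about to repeat, so the returned ring closes without duplicating
    the start point.  Pixels on one-pixel-wide protrusions legitimately
    appear more than once (the boundary walks out and back).
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return []
    start = (int(rows[0]), int(cols[0]))  # uppermost-leftmost foreground pixel
    h, w = mask.shape

    def is_fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and bool(mask[p[0], p[1]])

    boundary: List[Tuple[int, int]] = []
    cur = start
    search = 0  # start the clockwise scan at the West neighbor (background)
    first_state = None
    while True:
        d = -1
        for k in range(8):
            cand_d = (search + k) % 8
            cand = (cur[0] + _MOORE[cand_d][0], cur[1] + _MOORE[cand_d][1])
            if is_fg(cand):
                d = cand_d
                break
        if d < 0:  # isolated pixel
            return [start]
        if first_state is None:
            first_state = (cur, d)
        elif (cur, d) == first_state:
            break
        boundary.append(cur)
        cur = cand
        search = (d + 5) % 8  # one step clockwise past the backtrack direction
        if len(boundary) > 4 * mask.size:  # safety net; unreachable on valid input
            raise RuntimeError("boundary tracing failed to terminate")
    return boundary


def extract_contours(labels) -> Dict[int, Contour]:
    """Trace the outer boundary of every instance in a label map.

    Returns one clockwise, closed :class:`Contour` per instance id,
    via Moore-neighbor tracing under 8-connectivity.
    """
    lab = np.asarray(labels)
    out: Dict[int, Contour] = {}
    if lab.size == 0 or lab.max() == 0:
        return out
    objects = ndimage.find_objects(lab)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = lab[sl] == idx
        pts = _trace_moore(sub)
        if not pts:
            continue
        r0, c0 = sl[0].start, sl[1].start
        out[idx] = Contour(tuple((r + r0, c + c0) for r, c in pts), closed=True)
    return out


def pixel_area(labels, instance_id: int) -> int:
    """Pixel count of one instance (discrete region integral)."""
    lab = np.asarray(labels)
    n = int(np.count_nonzero(lab == instance_id)) if instance_id != 0 else 0
    if instance_id == 0 or n == 0:
        raise KeyError(f"instance {instance_id} not present in label map")
    return n


def pixel_perimeter(contour: Contour) -> float:
    """Polygonal length of a closed boundary ring.

    Axis steps count 1, diagonal steps sqrt(2); a single-pixel contour
    has zero length.
    """
    pts = contour.points
    if len(pts) == 1:
        return 0.0
    if not contour.closed:
        raise ValueError("perimeter requires a closed contour")
    total = 0.0
    for (r0, c0), (r1, c1) in zip(pts, pts[1:] + (pts[0],)):
        dr, dc = abs(r1 - r0), abs(c1 - c0)
        if dr > 1 or dc > 1:
            raise ValueError("consecutive contour points must be 8-neighbors")
        total += _SQRT2 if dr + dc == 2 else float(dr + dc)
    return total


def to_physical(area_px, perimeter_px, calib: Calibration) -> Tuple[float, float]:
    """Convert pixel measurements to physical units.

    ``area_cm2 = area_px * dx * dy``; perimeter converts with ``dx``
    alone (square-pixel assumption) — a warning is issued when
    ``dx != dy``.
    """
    if area_px < 0 or perimeter_px < 0:
        raise ValueError("area and perimeter must be non-negative")
    if calib.dx != calib.dy:
        warnings.warn("non-square pixels: perimeter converts with dx only")
    area = float(Fraction(int(area_px)) * calib.dx * calib.dy)
    perim = float(perimeter_px) * calib.dx_float
    return area, perim


def measure_instances(labels, calib: Calibration) -> List[LeafMeasurement]:
    """One :class:`LeafMeasurement` per instance, ordered by instance id.

    Area is the per-label pixel count, perimeter the traced-boundary
    length, centroid the mean pixel coordinate, bbox half-open.
    """
    lab = np.asarray(labels)
    out: List[LeafMeasurement] = []
    if lab.size == 0 or lab.max() == 0:
        return out
    contours = extract_contours(lab)
    ids = sorted(contours)
    counts = np.bincount(lab.ravel(), minlength=max(ids) + 1)
    centroids = ndimage.center_of_mass(lab > 0, lab, ids)
    objects = ndimage.find_objects(lab)
    for i, inst in enumerate(ids):
        perim_px = pixel_perimeter(contours[inst])
        area_cm2, perim_cm = to_physical(int(counts[inst]), perim_px, calib)
        sl = objects[inst - 1]
        out.append(LeafMeasurement(
            instance_id=inst,
            area_px=int(counts[inst]),
            perimeter_px=perim_px,
            area_cm2=area_cm2,
            perimeter_cm=perim_cm,
            centroid=(float(centroids[i][0]), float(centroids[i][1])),
            bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
        ))
    return out


_CSV_COLUMNS = ["instance_id", "frame", "time_h", "area_px", "area_cm2",
                "perimeter_px", "perimeter_cm", "centroid_row", "centroid_col", "bbox"]


def write_measurements_csv(path, measurements: Sequence[LeafMeasurement],
                           frame=None, time_h=None) -> pd.DataFrame:
    """Write measurements to CSV with a fixed column order.

    Floats are written at 6 significant digits; ``bbox`` is serialized
    as ``"r0:c0:r1:c1"``.  Returns the DataFrame that was written.
    """
    rows = []
    for m in measurements:
        rows.append({
            "instance_id": m.instance_id,
            "frame": frame,
            "time_h": time_h,
            "area_px": m.area_px,
            "area_cm2": m.area_cm2,
            "perimeter_px": m.perimeter_px,
            "perimeter_cm": m.perimeter_cm,
            "centroid_row": m.centroid[0],
            "centroid_col": m.centroid[1],
            "bbox": ":".join(str(v) for v in m.bbox),
        })
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")
    return df
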