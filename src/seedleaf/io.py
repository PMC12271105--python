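"""Readers and writers for the tool's on-disk formats.

Supported dialects: YOLO-style polygon TXT (one instance per line,
``class x1 y1 x2 y2 ...`` with coordinates normalized to [0, 1]), 8-bit
binary mask PNG ({0, 255}), 16-bit label-map PNG, measurement/track CSV,
and YAML/JSON run configuration.  Readers reject malformed records
rather than silently repairing them.

Denormalization follows the pixel-center convention: normalized x maps
to column ``x * width - 0.5``, so a polygon vertex at 0.5 sits exactly
between the two middle pixels of an even-width image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import yaml
from matplotlib.path import Path as MplPath
from PIL import Image

__all__ = [
    "PolygonAnnotation",
    "AnnotationError",
    "read_polygon_annotations",
    "write_polygon_annotations",
    "rasterize_polygons",
    "read_mask_png",
    "write_mask_png",
    "read_image",
    "write_image",
    "load_config",
]


class AnnotationError(ValueError):
    """Malformed or out-of-range annotation record."""


@dataclass(frozen=True)
class PolygonAnnotation:
    """One instance polygon: class id + normalized (x, y) vertices."""

    class_id: int
    vertices: Tuple[Tuple[float, float], ...]

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise AnnotationError("polygon needs at least 3 vertices")
        for x, y in self.vertices:
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise AnnotationError(f"vertex ({x}, {y}) outside [0, 1]")


def read_polygon_annotations(path) -> List[PolygonAnnotation]:
    """Parse a polygon TXT file; empty files are valid (no instances)."""
    path = Path(path)
    out: List[PolygonAnnotation] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) < 7 or len(tokens) % 2 == 0:
            raise AnnotationError(
                f"{path}:{lineno}: expected odd token count >= 7, got {len(tokens)}")
        try:
            cls = int(tokens[0])
            coords = [float(t) for t in tokens[1:]]
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: non-numeric token") from exc
        verts = tuple(zip(coords[0::2], coords[1::2]))
        try:
            out.append(PolygonAnnotation(class_id=cls, vertices=verts))
        except AnnotationError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_polygon_annotations(path, annotations: Sequence[PolygonAnnotation]):
    lines = []
    for ann in annotations:
        coords = " ".join(f"{v:.6f}" for xy in ann.vertices for v in xy)
        lines.append(f"{ann.class_id} {coords}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def rasterize_polygons(annotations: Sequence[PolygonAnnotation],
                       height: int, width: int) -> np.ndarray:
    """Fill polygons into a label map (ids 1..n in file order).

    Vertices are denormalized under the pixel-center convention and
    filled with the even-odd rule by testing each pixel center; later
    instances overwrite earlier ones where polygons overlap.  Polygons
    lying entirely outside the raster are dropped with a warning.
    """
    import warnings

    labels = np.zeros((height, width), dtype=np.int32)
    next_id = 1
    for ann in annotations:
        verts = np.array([(x * width - 0.5, y * height - 0.5) for x, y in ann.vertices])
        c0 = max(0, int(np.floor(verts[:, 0].min())))
        c1 = min(width, int(np.ceil(verts[:, 0].max())) + 1)
        r0 = max(0, int(np.floor(verts[:, 1].min())))
        r1 = min(height, int(np.ceil(verts[:, 1].max())) + 1)
        if r0 >= r1 or c0 >= c1:
            warnings.warn("polygon outside raster dropped")
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pts = np.column_stack([cc.ravel(), rr.ravel()])
        inside = MplPath(verts).contains_points(pts).reshape(rr.shape)
        if not inside.any():
            warnings.warn("polygon outside raster dropped")
            continue
        sub = labels[r0:r1, c0:c1]
        sub[inside] = next_id
        next_id += 1
    return labels


def write_mask_png(path, raster: np.ndarray):
    """Write a binary mask as 8-bit {0, 255} or a label map as 16-bit PNG."""
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise ValueError("mask raster must be 2-D")
    vmax = int(arr.max()) if arr.size else 0
    if vmax > 65535:
        raise ValueError("label map exceeds 16-bit PNG capacity")
    if set(np.unique(arr).tolist()) <= {0, 1}:
        Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(arr.astype(np.uint16)).save(path)


def read_mask_png(path) -> np.ndarray:
    """Read a mask PNG: {0, 255} files become binary {0, 1} uint8, other
    integer rasters come back as int32 label maps."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel mask PNG")
    uniq = set(np.unique(arr).tolist())
    if uniq <= {0, 255}:
        return (arr > 0).astype(np.uint8)
    return arr.astype(np.int32)


def read_image(path) -> np.ndarray:
    """Read a PNG/JPG image as uint8 (HxW or HxWx3)."""
    img = Image.open(path)
    if img.mode not in ("L", "RGB"):
        img = img.convert("RGB")
    return np.asarray(img)


def write_image(path, arr: np.ndarray):
    Image.fromarray(np.asarray(arr).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# Run configuration

_CONFIG_SCHEMA = {
    "calibration": {"Lx", "Ly", "width", "height"},
    "operators": {"se_size", "canny_low", "canny_high", "canny_sigma",
                  "marker_fraction", "min_area"},
    "tracking": {"max_displacement", "min_track_length", "interval_h"},
    "augmentation": {"gain", "gamma", "hue_shift", "sat_scale", "grayscale",
                     "blur_sigma", "motion_blur_len", "noise_sigma", "seed"},
    "output": {"dir"},
    "seed": None,
}


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration, rejecting unknown keys."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    for key, val in cfg.items():
        if key not in _CONFIG_SCHEMA:
            raise ValueError(f"{path}: unknown config key '{key}'")
        allowed = _CONFIG_SCHEMA[key]
        if allowed is not None:
            if not isinstance(val, dict):
                raise ValueError(f"{path}: '{key}' must be a mapping")
            unknown = set(val) - allowed
            if unknown:
                raise ValueError(f"{path}: unknown keys under '{key}': {sorted(unknown)}")
    return cfg
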