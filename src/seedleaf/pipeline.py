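"""Per-frame measurement workflow.

One frame runs through seven steps: load/rasterize the predicted mask,
refine it morphologically, remove the background, extract edges, split
touching instances with the distance-transform watershed, trace contours
and measure, then render a visual-mapping overlay.  Leaf area always
comes from the labeled region (a region integral), not from the edge
map, which is kept for visualization and boundary cross-checks.

When no trained detector output is available, :func:`fallback_segment`
produces a mask from the excess-green vegetation index (2G - R - B) so
the pipeline runs end-to-end on raw color images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from . import imops
from .imops import StructuringElement, DegenerateImageError
from .io import PolygonAnnotation, rasterize_polygons
from .quantify import Calibration, Contour, LeafMeasurement, extract_contours, \
    measure_instances

__all__ = [
    "PipelineConfig",
    "FrameResult",
    "refine_mask",
    "remove_background",
    "fallback_segment",
    "process_frame",
    "overlay_visualization",
]

# fixed per-instance palette for deterministic overlays (RGB)
_PALETTE = [
    (230, 60, 60), (60, 120, 230), (240, 180, 40), (170, 70, 200),
    (40, 200, 200), (240, 120, 180), (140, 220, 70), (250, 140, 50),
]


@dataclass(frozen=True)
class PipelineConfig:
    """Operator parameters for one run."""

    se_size: int = 3
    canny_low: Optional[float] = None    # None -> automatic (Otsu of magnitude)
    canny_high: Optional[float] = None
    canny_sigma: float = 1.0
    marker_fraction: float = 0.4
    min_area: int = 20
    overlay_alpha: float = 0.4

    @property
    def se(self) -> StructuringElement:
        return StructuringElement.square(self.se_size)


@dataclass
class FrameResult:
    """All intermediates and measurements for one frame."""

    frame_id: Union[int, str]
    time_h: float
    refined_mask: np.ndarray
    instance_labels: np.ndarray
    edges: np.ndarray
    contours: Dict[int, Contour]
    measurements: List[LeafMeasurement]
    overlay_path: Optional[str] = None


def refine_mask(raw: np.ndarray, se: Optional[StructuringElement] = None) -> np.ndarray:
    """Morphological cleanup: opening (removes speckle noise) followed by
    closing (bridges boundary cracks)."""
    se = se or StructuringElement.square(3)
    return imops.closing(imops.opening(raw, se), se)


def remove_background(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every pixel outside the mask; pixels inside pass through."""
    img = np.asarray(image)
    m = np.asarray(mask) > 0
    if img.shape[:2] != m.shape:
        raise ValueError("image and mask dimensions differ")
    if img.ndim == 3:
        return np.where(m[..., None], img, 0)
    return np.where(m, img, 0)


def fallback_segment(image: np.ndarray,
                     se: Optional[StructuringElement] = None) -> np.ndarray:
    """Model-free leaf segmentation from the excess-green index.

    Computes ExG = 2G - R - B per pixel, binarizes it with Otsu's
    threshold and refines the result morphologically.  A stand-in for a
    trained detector that keeps the measurement chain runnable on raw
    tray images.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("fallback segmentation needs a color (RGB) image")
    rgb = img.astype(np.float64)
    exg = 2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    try:
        _, binary = imops.otsu_threshold(exg)
    except DegenerateImageError:
        # constant vegetation index: all-foreground if green-dominant
        value = float(exg.ravel()[0])
        return np.full(exg.shape, 1 if value > 0 else 0, dtype=np.uint8)
    return refine_mask(binary, se)


def process_frame(image: np.ndarray,
                  polygons_or_mask: Union[Sequence[PolygonAnnotation], np.ndarray],
                  calib: Calibration,
                  cfg: Optional[PipelineConfig] = None,
                  frame_id: Union[int, str] = 0,
                  time_h: float = 0.0) -> FrameResult:
    """Run the full per-frame workflow and return every intermediate.

    ``polygons_or_mask`` is either a list of polygon annotations (the
    detector-export dialect) or an already-rasterized binary/labeled
    mask of the same height and width as the image.  An empty mask is
    valid and yields zero instances.
    """
    cfg = cfg or PipelineConfig()
    img = np.asarray(image)
    h, w = img.shape[:2]
    if isinstance(polygons_or_mask, np.ndarray):
        if polygons_or_mask.shape != (h, w):
            raise ValueError("mask and image dimensions differ")
        raw = (polygons_or_mask > 0).astype(np.uint8)
    else:
        raw = (rasterize_polygons(polygons_or_mask, h, w) > 0).astype(np.uint8)
    refined = refine_mask(raw, cfg.se)
    isolated = remove_background(img, refined)
    gray = isolated.astype(np.float64).mean(axis=2) if isolated.ndim == 3 \
        else isolated.astype(np.float64)
    edges = imops.canny(gray, low=cfg.canny_low, high=cfg.canny_high,
                        sigma=cfg.canny_sigma)
    labels = imops.split_instances(refined, marker_fraction=cfg.marker_fraction,
                                   min_area=cfg.min_area)
    contours = extract_contours(labels)
    measurements = measure_instances(labels, calib)
    return FrameResult(frame_id=frame_id, time_h=time_h, refined_mask=refined,
                       instance_labels=labels, edges=edges, contours=contours,
                       measurements=measurements)


def overlay_visualization(image: np.ndarray, result: FrameResult,
                          alpha: float = 0.4) -> np.ndarray:
    """Visual mapping: semi-transparent instance tint, contour polylines
    and per-instance area/perimeter text on a copy of the input.

    Rendering is fully deterministic (fixed palette, fixed font), so
    identical inputs yield byte-identical overlays.
    """
    from PIL import Image, ImageDraw

    img = np.asarray(image)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    out = img.astype(np.float64).copy()
    labels = result.instance_labels
    for m in result.measurements:
        color = np.array(_PALETTE[(m.instance_id - 1) % len(_PALETTE)], dtype=np.float64)
        sel = labels == m.instance_id
        out[sel] = (1.0 - alpha) * out[sel] + alpha * color
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    pil = Image.fromarray(out)
    draw = ImageDraw.Draw(pil)
    for m in result.measurements:
        color = _PALETTE[(m.instance_id - 1) % len(_PALETTE)]
        pts = result.contours[m.instance_id].points
        for r, c in pts:
            draw.point((c, r), fill=color)
        text = f"{m.instance_id}: {m.area_cm2:.2f} cm2 / {m.perimeter_cm:.2f} cm"
        draw.text((m.bbox[1], max(0, m.bbox[0] - 12)), text, fill=color)
    header = f"frame {result.frame_id}  t={result.time_h:.2f} h  n={len(result.measurements)}"
    draw.text((4, 2), header, fill=(255, 255, 255))
    return np.asarray(pil)
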