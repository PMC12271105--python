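"""Classical image operators for leaf-mask post-processing.

Everything in this module is deterministic and defined on plain numpy
rasters using (row, col) indexing with a top-left origin; wherever the
field writes ``(x, y)``, ``x`` is the column and ``y`` the row.

The operators cover the post-processing chain used to turn a coarse
segmentation mask into measurable leaf instances:

* grayscale/binary **morphology** (erosion, dilation, opening, closing),
* **Otsu** binarization by exhaustive maximization of the between-class
  variance,
* **Canny** edge extraction (Gaussian-smoothed Sobel gradients,
  non-maximum suppression, double-threshold hysteresis),
* the exact Euclidean **distance transform** (two-pass parabolic
  lower-envelope algorithm),
* marker-based **watershed** (Meyer priority flood on the negated
  distance map), and a marker-construction wrapper,
  :func:`split_instances`, that separates touching leaves.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "StructuringElement",
    "GradientField",
    "DegenerateImageError",
    "erode",
    "dilate",
    "opening",
    "closing",
    "otsu_threshold",
    "gradient",
    "canny",
    "distance_transform",
    "watershed",
    "split_instances",
]

# 8-connected neighborhood, used by watershed and hysteresis.
_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class DegenerateImageError(ValueError):
    """Raised when an operator has no meaningful answer (e.g. Otsu on a
    constant image, distance transform of an all-foreground mask)."""


@dataclass(frozen=True)
class StructuringElement:
    """Neighborhood over which morphological min/max operators act.

    ``offsets`` are (drow, dcol) displacements relative to the anchor at
    (0, 0).  The default constructor :meth:`square` yields the 3x3
    8-connected square, the smallest element that removes single-pixel
    specks and closes single-pixel gaps at seedling scale.
    """

    offsets: tuple = field(default_factory=tuple)

    def __post_init__(self):
        offs = tuple((int(r), int(c)) for r, c in self.offsets)
        if not offs:
            raise ValueError("structuring element must be non-empty")
        object.__setattr__(self, "offsets", offs)

    @classmethod
    def square(cls, size: int = 3) -> "StructuringElement":
        if size < 1 or size % 2 == 0:
            raise ValueError("square structuring element needs an odd size >= 1")
        k = size // 2
        return cls(tuple((r, c) for r in range(-k, k + 1) for c in range(-k, k + 1)))

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "StructuringElement":
        m = np.asarray(mask)
        if m.ndim != 2 or m.shape[0] % 2 == 0 or m.shape[1] % 2 == 0:
            raise ValueError("structuring element mask must be 2-D with odd sides")
        cr, cc = m.shape[0] // 2, m.shape[1] // 2
        rows, cols = np.nonzero(m)
        return cls(tuple(zip((rows - cr).tolist(), (cols - cc).tolist())))

    @property
    def reflected(self) -> "StructuringElement":
        return StructuringElement(tuple((-r, -c) for r, c in self.offsets))


@dataclass(frozen=True)
class GradientField:
    """Image gradient: signed partials, magnitude and orientation.

    ``magnitude = hypot(gx, gy)`` and ``orientation = atan2(gy, gx)``
    hold everywhere by construction.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray


def _check_image(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("expected a non-empty 2-D image")
    return arr


def _minmax_filter(img, se, take_max: bool, padding: str) -> np.ndarray:
    arr = _check_image(img)
    if not isinstance(se, StructuringElement):
        raise TypeError("se must be a StructuringElement")
    if padding not in ("ignore", "zero"):
        raise ValueError("padding must be 'ignore' or 'zero'")
    h, w = arr.shape
    work = arr.astype(np.float64, copy=False)
    fill = -np.inf if take_max else np.inf
    out = np.full((h, w), fill)
    for dr, dc in se.offsets:
        # output[r, c] samples input[r+dr, c+dc]
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        src = work[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        dst = out[r0:r1, c0:c1]
        np.maximum(dst, src, out=dst) if take_max else np.minimum(dst, src, out=dst)
    if padding == "zero":
        # out-of-bounds samples contribute the value 0
        n_inb = np.zeros((h, w), dtype=int)
        for dr, dc in se.offsets:
            r0, r1 = max(0, -dr), min(h, h - dr)
            c0, c1 = max(0, -dc), min(w, w - dc)
            if r0 < r1 and c0 < c1:
                n_inb[r0:r1, c0:c1] += 1
        touched = n_inb < len(se.offsets)
        if take_max:
            out[touched] = np.maximum(out[touched], 0.0)
        else:
            out[touched] = np.minimum(out[touched], 0.0)
    # a pixel whose whole neighborhood fell outside keeps its own value
    bad = ~np.isfinite(out)
    if bad.any():
        out[bad] = work[bad]
    if arr.dtype.kind in "biu":
        return np.rint(out).astype(arr.dtype)
    return out.astype(arr.dtype, copy=False)


def erode(img, se: StructuringElement | None = None, padding: str = "ignore"):
    """Morphological erosion: min of the input over the structuring element.

    ``padding='ignore'`` (default) drops out-of-bounds samples so shapes
    touching the crop boundary are not artificially eroded;
    ``padding='zero'`` treats the outside as background.
    """
    return _minmax_filter(img, se or StructuringElement.square(3), False, padding)


def dilate(img, se: StructuringElement | None = None, padding: str = "ignore"):
    """Morphological dilation: max of the input over the structuring element."""
    return _minmax_filter(img, se or StructuringElement.square(3), True, padding)


def opening(img, se: StructuringElement | None = None, padding: str = "ignore"):
    """Erosion followed by dilation; removes specks smaller than the element.

    Anti-extensive and idempotent on binary input.
    """
    se = se or StructuringElement.square(3)
    return dilate(erode(img, se, padding), se, padding)


def closing(img, se: StructuringElement | None = None, padding: str = "ignore"):
    """Dilation followed by erosion; bridges gaps narrower than the element.

    Extensive and idempotent on binary input.
    """
    se = se or StructuringElement.square(3)
    return erode(dilate(img, se, padding), se, padding)


def _quantize(img: np.ndarray, levels: int = 256):
    """Map an image onto integer histogram levels.

    Integer-valued non-negative images are used as-is (so adding a
    constant c to every pixel shifts the Otsu threshold by exactly c);
    anything else is linearly rescaled onto [0, levels-1].
    """
    arr = _check_image(img).astype(np.float64, copy=False)
    if not np.isfinite(arr).all():
        raise ValueError("image intensities must be finite")
    is_integral = np.all(arr == np.rint(arr)) and arr.min() >= 0 and arr.max() < 65536
    if is_integral:
        return np.rint(arr).astype(np.int64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.int64)
    return np.rint((arr - lo) / (hi - lo) * (levels - 1)).astype(np.int64)


def otsu_threshold(img, levels: int = 256):
    """Otsu's automatic threshold by exhaustive between-class-variance scan.

    Scans every candidate threshold t and maximizes

        sigma_B^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

    where w0/w1 are the class probabilities of pixels <= t and > t and
    mu0/mu1 the class mean levels.  Returns ``(t_star, binary)`` where
    ``t_star`` is the smallest maximizing level and ``binary`` marks
    pixels strictly above ``t_star``.

    Raises
    ------
    DegenerateImageError
        If the image has a single distinct intensity (no valid split).
    """
    q = _quantize(img, levels)
    if q.min() == q.max():
        raise DegenerateImageError("constant image has no Otsu threshold")
    hist = np.bincount(q.ravel())
    p = hist / hist.sum()
    i = np.arange(len(hist))
    w0 = np.cumsum(p)
    mu_cum = np.cumsum(i * p)
    mu_total = mu_cum[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(len(hist))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        sigma_b[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    t_star = int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer
    binary = (q > t_star).astype(np.uint8)
    return t_star, binary


# 3x3 Sobel derivative kernels; _SOBEL_X estimates d/dx (x = column).
_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


def gradient(img, sigma: float = 1.0) -> GradientField:
    """Sobel gradient of the (optionally Gaussian-smoothed) image.

    ``sigma <= 0`` skips smoothing.  Border samples are replicated so a
    constant image has an exactly zero gradient everywhere.
    """
    arr = _check_image(img).astype(np.float64, copy=False)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image smaller than the 3x3 derivative operator")
    if sigma > 0:
        arr = ndimage.gaussian_filter(arr, sigma, mode="nearest")
    gx = ndimage.correlate(arr, _SOBEL_X, mode="nearest")
    gy = ndimage.correlate(arr, _SOBEL_Y, mode="nearest")
    return GradientField(gx=gx, gy=gy, magnitude=np.hypot(gx, gy),
                         orientation=np.arctan2(gy, gx))


def _nms(mag: np.ndarray, orient: np.ndarray) -> np.ndarray:
    """Non-maximum suppression with 4-sector direction quantization.

    Of two equal-magnitude neighbors along the gradient direction the one
    with the smaller (row, col) survives, keeping ridges one pixel wide.
    """
    h, w = mag.shape
    padded = np.pad(mag, 1, mode="constant")
    # sector index from orientation folded to [0, pi)
    ang = np.mod(orient, np.pi)
    sector = np.floor((ang + np.pi / 8) / (np.pi / 4)).astype(int) % 4
    # sector -> (dr, dc) step along the gradient direction
    steps = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    keep = np.zeros((h, w), dtype=bool)
    for s, (dr, dc) in steps.items():
        sel = sector == s
        fwd = padded[1 + dr:h + 1 + dr, 1 + dc:w + 1 + dc]
        bwd = padded[1 - dr:h + 1 - dr, 1 - dc:w + 1 - dc]
        keep |= sel & (mag >= fwd) & (mag > bwd)
    keep &= mag > 0
    return keep


def canny(img, low: float | None = None, high: float | None = None,
          sigma: float = 1.0) -> np.ndarray:
    """Canny edge map: gradient, non-maximum suppression, hysteresis.

    When thresholds are omitted, ``high`` defaults to the Otsu threshold
    of the gradient-magnitude histogram and ``low = 0.5 * high`` — a
    parameter-free default for leaf boundaries of varying contrast.
    Edge pixels are magnitude maxima along the gradient direction that
    are >= ``low`` and 8-connected to a pixel >= ``high``.
    """
    g = gradient(img, sigma=sigma)
    mag = g.magnitude
    if mag.max() == 0:
        return np.zeros(mag.shape, dtype=np.uint8)
    if high is None:
        # Otsu on the magnitude histogram, mapped back to magnitude units
        scale = mag.max() / 255.0
        t, _ = otsu_threshold(np.rint(mag / scale))
        high = t * scale
        low = 0.5 * high if low is None else low
    if low is None:
        low = 0.5 * high
    if low < 0 or low > high:
        raise ValueError("need 0 <= low <= high")
    keep = _nms(mag, g.orientation)
    weak = keep & (mag >= low)
    strong = keep & (mag >= high)
    lab, n = ndimage.label(weak, structure=np.ones((3, 3)))
    if n == 0:
        return np.zeros(mag.shape, dtype=np.uint8)
    has_strong = np.zeros(n + 1, dtype=bool)
    has_strong[np.unique(lab[strong])] = True
    has_strong[0] = False
    return has_strong[lab].astype(np.uint8)


def _edt_1d_sq(f: np.ndarray) -> np.ndarray:
    """1-D squared distance transform of a sampled function f (lower
    envelope of parabolas); f entries may be +inf."""
    n = len(f)
    d = np.full(n, np.inf)
    v = np.zeros(n, dtype=int)
    z = np.full(n + 1, np.inf)
    finite = np.nonzero(np.isfinite(f))[0]
    if len(finite) == 0:
        return d
    k = 0
    v[0] = finite[0]
    z[0] = -np.inf
    z[1] = np.inf
    for q in finite[1:]:
        s = ((f[q] + q * q) - (f[v[k]] + v[k] * v[k])) / (2 * q - 2 * v[k])
        while s <= z[k]:
            k -= 1
            s = ((f[q] + q * q) - (f[v[k]] + v[k] * v[k])) / (2 * q - 2 * v[k])
        k += 1
        v[k] = q
        z[k] = s
        z[k + 1] = np.inf
    k = 0
    for q in range(n):
        while z[k + 1] < q:
            k += 1
        d[q] = (q - v[k]) ** 2 + f[v[k]]
    return d


def distance_transform(mask) -> np.ndarray:
    """Exact Euclidean distance from each pixel to the nearest background.

    Two-pass algorithm: a 1-D vertical scan per column followed by a
    parabolic lower-envelope pass per row, giving the exact Euclidean
    metric (no chamfer approximation) so watershed markers sit on true
    distance maxima.  Background pixels map to exactly 0.
    """
    arr = _check_image(mask)
    fg = arr > 0
    if not fg.any():
        return np.zeros(arr.shape, dtype=np.float64)
    if fg.all():
        raise DegenerateImageError("all-foreground mask: distance undefined")
    h, w = arr.shape
    # pass 1: per-column vertical distances
    g = np.where(fg, np.inf, 0.0)
    for r in range(1, h):
        g[r] = np.minimum(g[r], g[r - 1] + 1.0)
    for r in range(h - 2, -1, -1):
        g[r] = np.minimum(g[r], g[r + 1] + 1.0)
    # pass 2: per-row lower envelope over squared vertical distances
    g2 = g * g
    out = np.empty((h, w), dtype=np.float64)
    for r in range(h):
        out[r] = _edt_1d_sq(g2[r])
    np.sqrt(out, out=out)
    out[~fg] = 0.0
    return out


def watershed(dist, markers) -> np.ndarray:
    """Marker-based watershed by Meyer priority flood on the negated
    distance map.

    Foreground is ``dist > 0``.  Pixels flood from the markers in order
    of decreasing distance (8-connectivity).  Contested equal-priority
    pixels go to the neighbor with the larger distance value, ties to
    the lower label id, so the foreground reachable from markers is
    totally partitioned and per-label pixel counts are conserved.
    """
    d = _check_image(dist).astype(np.float64, copy=False)
    m = _check_image(markers)
    if m.shape != d.shape:
        raise ValueError("markers and distance map must share shape")
    fg = d > 0
    labels = np.zeros(d.shape, dtype=np.int32)
    if not (m > 0).any():
        warnings.warn("watershed called with no markers; returning background")
        return labels
    if ((m > 0) & ~fg).any():
        raise ValueError("marker outside the foreground")
    labels[m > 0] = m[m > 0]
    h, w = d.shape
    heap = []
    counter = 0
    seed_rows, seed_cols = np.nonzero(m > 0)
    for r, c in zip(seed_rows.tolist(), seed_cols.tolist()):
        lab = int(m[r, c])
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and fg[rr, cc] and labels[rr, cc] == 0:
                heapq.heappush(heap, (-d[rr, cc], -d[r, c], lab, counter, rr, cc))
                counter += 1
    while heap:
        _, _, lab, _, r, c = heapq.heappop(heap)
        if labels[r, c] != 0:
            continue
        labels[r, c] = lab
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and fg[rr, cc] and labels[rr, cc] == 0:
                heapq.heappush(heap, (-d[rr, cc], -d[r, c], lab, counter, rr, cc))
                counter += 1
    return labels


def split_instances(mask, marker_fraction: float = 0.4, min_area: int = 20) -> np.ndarray:
    """Partition a binary mask into leaf instances via distance-transform
    watershed.

    Per 8-connected component, markers are the connected components of
    ``{d >= marker_fraction * max(d)}`` (the threshold is normalized per
    component so large and small leaves are treated alike); watershed
    then floods the component from those markers.  Instances smaller
    than ``min_area`` pixels are discarded.  Labels are consecutive
    ``1..n`` in deterministic raster/component order.
    """
    if not 0 < marker_fraction <= 1:
        raise ValueError("marker_fraction must be in (0, 1]")
    arr = _check_image(mask)
    fg = (arr > 0)
    out = np.zeros(arr.shape, dtype=np.int32)
    comps, ncomp = ndimage.label(fg, structure=np.ones((3, 3)))
    next_label = 1
    for idx, sl in enumerate(ndimage.find_objects(comps), start=1):
        sub = comps[sl] == idx
        padded = np.pad(sub, 1)  # guarantees background for the EDT
        d = distance_transform(padded.astype(np.uint8))
        dmax = d.max()
        marker_mask = d >= marker_fraction * dmax
        markers, nmark = ndimage.label(marker_mask, structure=np.ones((3, 3)))
        markers = np.where(markers > 0, markers + (next_label - 1), 0).astype(np.int32)
        ws = watershed(d, markers)
        inner = ws[1:-1, 1:-1]
        region = out[sl]
        region[sub] = inner[sub]
        next_label += nmark
    # area filter + consecutive relabeling
    if next_label > 1:
        counts = np.bincount(out.ravel(), minlength=next_label)
        keep = counts >= min_area
        keep[0] = False
        remap = np.zeros(next_label, dtype=np.int32)
        remap[keep] = np.arange(1, keep.sum() + 1)
        out = remap[out]
    return out
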