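"""Deterministic synthetic germination-tray generator.

Renders top-down tray images plus pixel-perfect instance ground truth so
the whole measurement chain is testable without any captured data.  The
emulated setup: a 25 cm x 25 cm tray imaged at 1500 x 1500 px, seeds in
a 6 x 6 grid, each germinating into a cotyledon pair (two leaf
instances), imaged on a fixed cadence from sowing.  Leaves are modelled
as a rotated two-lobed shape (union of two ellipses joined near the
hypocotyl) — five parameters that reproduce the overlap/adhesion failure
modes of real seedling imagery without attempting photorealism.

Leaf areas follow logistic growth profiles (rapid early enlargement,
then gradual slowing); photometric augmentations (exposure, color
jitter, grayscale, blur, noise) perturb the rendered image only, so
ground truth stays valid.

All randomness flows from the single ``SceneSpec.seed`` through named
substreams (layout / shape / photometry / frame jitter); identical specs
produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .quantify import Calibration, make_calibration, _trace_moore

__all__ = [
    "SceneSpec",
    "GrowthProfile",
    "AugmentationSpec",
    "Scene",
    "render_scene",
    "grow_series",
    "augment",
    "default_profiles",
    "logistic_area",
    "scene_calibration",
]

#: leaves smaller than this render unreliably and are treated as not yet emerged
MIN_RENDER_AREA_PX = 30

_LOBE_RATIO = 0.62   # semi-minor / semi-major axis of each ellipse lobe
_LOBE_OFFSET = 0.33  # lobe center offset along the leaf axis, in semi-major units
_LOBE_SPAN = 1.0 + _LOBE_OFFSET  # leaf half-extent along its axis, in semi-major units


@dataclass(frozen=True)
class SceneSpec:
    """Tray geometry and acquisition conditions for one synthetic scene."""

    tray_px: Tuple[int, int] = (1500, 1500)       # (height, width)
    tray_cm: Tuple[float, float] = (25.0, 25.0)   # (Ly, Lx)
    grid: Tuple[int, int] = (6, 6)                # seed rows x cols
    n_leaves_per_seed: int = 2                    # cotyledon pair
    overlap_fraction: float = 0.0                 # fraction of seeds with touching pairs
    margin_frac: float = 0.08                     # tray border kept free of seeds
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.grid[0] < 1 or self.grid[1] < 1 or self.n_leaves_per_seed < 1:
            raise ValueError("grid and leaves-per-seed must be positive")

    @property
    def n_seeds(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def n_leaves(self) -> int:
        return self.n_seeds * self.n_leaves_per_seed


@dataclass(frozen=True)
class GrowthProfile:
    """Logistic area trajectory of one leaf.

    ``area(t) = a_max_cm2 / (1 + exp(-k_per_h * (t - t0_h)))`` for
    ``t >= emergence_h``, zero before emergence.
    """

    a_max_cm2: float
    k_per_h: float
    t0_h: float
    emergence_h: float = 48.0

    def __post_init__(self):
        if self.a_max_cm2 <= 0 or self.k_per_h <= 0:
            raise ValueError("a_max and k must be positive")


@dataclass(frozen=True)
class AugmentationSpec:
    """Photometric perturbations applied in a fixed order:
    exposure -> color -> grayscale -> blur -> noise.

    All parameters optional; geometry is never altered, so instance
    ground truth remains valid for augmented images.  ``noise_sigma``
    is on the [0, 1] intensity scale (e.g. 8/255).
    """

    gain: Optional[float] = None          # multiplicative exposure, (0.2, 5)
    gamma: Optional[float] = None         # exposure curve, (0.2, 5)
    hue_shift: Optional[float] = None     # in (-0.5, 0.5) hue turns
    sat_scale: Optional[float] = None     # in (0, 3)
    grayscale: bool = False
    blur_sigma: Optional[float] = None    # Gaussian, px, [0, 10]
    motion_blur_len: Optional[int] = None # horizontal box kernel, px, [1, 31]
    noise_sigma: Optional[float] = None   # Gaussian, [0, 0.2] of full scale
    seed: int = 0

    def validate(self):
        checks = [
            (self.gain, 0.2, 5.0, "gain"),
            (self.gamma, 0.2, 5.0, "gamma"),
            (self.hue_shift, -0.5, 0.5, "hue_shift"),
            (self.sat_scale, 0.0, 3.0, "sat_scale"),
            (self.blur_sigma, 0.0, 10.0, "blur_sigma"),
            (self.noise_sigma, 0.0, 0.2, "noise_sigma"),
        ]
        for val, lo, hi, name in checks:
            if val is not None and not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside safe range [{lo}, {hi}]")
        if self.motion_blur_len is not None and not 1 <= self.motion_blur_len <= 31:
            raise ValueError("motion_blur_len outside safe range [1, 31]")


@dataclass(frozen=True)
class Scene:
    """One rendered frame with its ground truth."""

    time_h: float
    image: np.ndarray                 # uint8 HxWx3
    labels: np.ndarray                # int32, persistent leaf ids, 0 = background
    annotations: List                 # PolygonAnnotation per visible instance
    true_areas_px: dict               # leaf_id -> exact rendered pixel count
    true_areas_cm2: dict              # leaf_id -> exact rendered physical area


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def scene_calibration(spec: SceneSpec) -> Calibration:
    return make_calibration(Lx=spec.tray_cm[1], Ly=spec.tray_cm[0],
                            width=spec.tray_px[1], height=spec.tray_px[0])


def logistic_area(profile: GrowthProfile, t_h: float) -> float:
    """Leaf area (cm^2) at time ``t_h`` hours after sowing."""
    if t_h < profile.emergence_h:
        return 0.0
    return profile.a_max_cm2 / (1.0 + math.exp(-profile.k_per_h * (t_h - profile.t0_h)))


def default_profiles(spec: SceneSpec) -> List[GrowthProfile]:
    """Realistic per-leaf growth profiles for a broccoli germination assay.

    Asymptotic cotyledon areas around 0.5-1.0 cm^2 (which also fit a
    6 x 6 grid cell on a 25 cm tray), growth-rate constants 0.08-0.16
    per hour, inflection between 75 and 95 h and emergence between 48
    and 60 h, drawn from the spec's shape substream.
    """
    rng = _rng(spec.seed, 1)
    out = []
    for _ in range(spec.n_leaves):
        out.append(GrowthProfile(
            a_max_cm2=float(rng.uniform(0.5, 1.0)),
            k_per_h=float(rng.uniform(0.08, 0.16)),
            t0_h=float(rng.uniform(75.0, 95.0)),
            emergence_h=float(rng.uniform(48.0, 60.0)),
        ))
    return out


@dataclass(frozen=True)
class _LeafSite:
    leaf_id: int
    seed_center: Tuple[float, float]  # (row, col)
    side: int                         # -1 / +1 along the pair axis
    theta: float                      # pair axis angle (radians)
    overlapping: bool


def _layout(spec: SceneSpec) -> List[_LeafSite]:
    """Grid placement of seeds and their leaves; all draws from the
    layout substream in a fixed order so layout is independent of areas."""
    rng = _rng(spec.seed, 0)
    h, w = spec.tray_px
    gr, gc = spec.grid
    m_r, m_c = h * spec.margin_frac, w * spec.margin_frac
    cell_h = (h - 2 * m_r) / gr
    cell_w = (w - 2 * m_c) / gc
    n_overlap = int(round(spec.overlap_fraction * spec.n_seeds))
    overlap_seeds = set(rng.choice(spec.n_seeds, size=n_overlap, replace=False).tolist())
    sites: List[_LeafSite] = []
    leaf_id = 1
    for i in range(gr):
        for j in range(gc):
            s_idx = i * gc + j
            cr = m_r + (i + 0.5) * cell_h + rng.uniform(-0.04, 0.04) * cell_h
            cc = m_c + (j + 0.5) * cell_w + rng.uniform(-0.04, 0.04) * cell_w
            theta = rng.uniform(0, np.pi)
            sides = [-1, 1][: spec.n_leaves_per_seed] or [-1]
            for side in sides:
                sites.append(_LeafSite(leaf_id, (cr, cc), side, theta,
                                       s_idx in overlap_seeds))
                leaf_id += 1
    return sites


def _leaf_pixels(center: Tuple[float, float], theta: float, a: float,
                 shape: Tuple[int, int]):
    """Rasterize one two-lobed leaf: rows/cols of pixels whose centers
    fall inside the union of the two ellipse lobes."""
    b = _LOBE_RATIO * a
    s = _LOBE_OFFSET * a
    cr, cc = center
    ext = _LOBE_SPAN * a + 1.0
    r0 = max(0, int(math.floor(cr - ext)))
    r1 = min(shape[0], int(math.ceil(cr + ext)) + 1)
    c0 = max(0, int(math.floor(cc - ext)))
    c1 = min(shape[1], int(math.ceil(cc + ext)) + 1)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    dy = rr - cr
    dx = cc_grid - cc
    # rotate into the leaf frame: u along the leaf axis
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (((u - s) / a) ** 2 + (v / b) ** 2 <= 1.0) | \
             (((u + s) / a) ** 2 + (v / b) ** 2 <= 1.0)
    return rr[inside], cc_grid[inside]


def _solve_scale(center, theta, target_px: int, shape, a_max: float) -> float:
    """Bisection on the semi-major axis so the rasterized pixel count
    hits ``target_px`` (within ~1% for leaves of a few hundred px)."""
    lo, hi = 0.5, a_max
    n_hi = len(_leaf_pixels(center, theta, hi, shape)[0])
    if n_hi < target_px:
        raise ValueError(f"requested area {target_px} px too large for grid cell")
    best = (abs(n_hi - target_px), hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        n = len(_leaf_pixels(center, theta, mid, shape)[0])
        if abs(n - target_px) < best[0]:
            best = (abs(n - target_px), mid)
        if n < target_px:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return best[1]


def _pair_offset(a: float, overlapping: bool) -> float:
    """Distance from seed center to each leaf center along the pair axis."""
    gap = -0.5 if overlapping else 4.0  # px between facing leaf tips
    return _LOBE_SPAN * a + 0.5 * gap


def _polygon_from_instance(mask: np.ndarray, h: int, w: int):
    """Normalized boundary polygon of one instance (pixel-center convention)."""
    from .io import PolygonAnnotation  # deferred: io imports nothing from here
    pts = _trace_moore(mask)
    if len(pts) < 3:
        return None
    verts = tuple(((c + 0.5) / w, (r + 0.5) / h) for r, c in pts)
    return PolygonAnnotation(class_id=0, vertices=verts)


def render_scene(spec: SceneSpec, areas_px: Sequence[float],
                 _jitter: Optional[np.ndarray] = None,
                 _time_h: float = 0.0,
                 _fixed_offsets: Optional[Sequence[float]] = None) -> Scene:
    """Render one tray frame.

    ``areas_px`` gives the target rendered area for every leaf site (one
    entry per leaf, row-major over the seed grid, pair order fixed);
    entries below :data:`MIN_RENDER_AREA_PX` leave that leaf absent.
    Returns the color image, the instance ground truth (persistent leaf
    ids) and per-instance boundary polygons.

    ``_fixed_offsets`` pins each leaf's center at a fixed distance from
    its seed (used by :func:`grow_series` so centroids stay put while
    areas change); by default the offset adapts to the rendered size so
    pair tips sit at their specified gap.
    """
    sites = _layout(spec)
    if len(areas_px) != len(sites):
        raise ValueError(f"need {len(sites)} target areas, got {len(areas_px)}")
    h, w = spec.tray_px
    gr, gc = spec.grid
    cell = min((h - 2 * h * spec.margin_frac) / gr, (w - 2 * w * spec.margin_frac) / gc)
    a_max = 0.48 * cell / (2 * _LOBE_SPAN)
    labels = np.zeros((h, w), dtype=np.int32)
    jitter = _jitter if _jitter is not None else np.zeros((len(sites), 2))
    for site, target, jit in zip(sites, areas_px, jitter):
        if target < MIN_RENDER_AREA_PX:
            continue
        # leaf center: seed center +/- pair offset along the pair axis.
        # The offset depends on the solved scale, so place-and-solve twice:
        # the second pass uses the converged semi-major axis.
        a = math.sqrt(target / (math.pi * _LOBE_RATIO * 1.55))
        fixed_off = None if _fixed_offsets is None else _fixed_offsets[site.leaf_id - 1]
        for _ in range(2):
            off = fixed_off if fixed_off is not None else _pair_offset(a, site.overlapping)
            cr = site.seed_center[0] + site.side * off * math.sin(site.theta) + jit[0]
            cc = site.seed_center[1] + site.side * off * math.cos(site.theta) + jit[1]
            a = _solve_scale((cr, cc), site.theta, int(round(target)), (h, w), a_max)
            if fixed_off is not None:
                break
        rows, cols = _leaf_pixels((cr, cc), site.theta, a, (h, w))
        labels[rows, cols] = site.leaf_id  # later leaves overwrite on overlap
    # ---- photometry ----
    prng = _rng(spec.seed, 2)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / ((h / 2) ** 2 + (w / 2) ** 2)
    vignette = 1.0 - 0.12 * r2
    image = np.empty((h, w, 3), dtype=np.float64)
    image[..., 0] = 128.0
    image[..., 1] = 126.0
    image[..., 2] = 122.0
    image *= vignette[..., None]
    # ungerminated seeds as small brown disks (distractors for the
    # vegetation-index fallback; drawn under the leaves)
    seen = set()
    for site in sites:
        if site.seed_center in seen:
            continue
        seen.add(site.seed_center)
        sr, sc = site.seed_center
        rr, cc2 = np.mgrid[max(0, int(sr) - 8):min(h, int(sr) + 9),
                           max(0, int(sc) - 8):min(w, int(sc) + 9)]
        disk = (rr - sr) ** 2 + (cc2 - sc) ** 2 <= 6.0 ** 2
        keep = disk & (labels[rr, cc2] == 0)
        image[rr[keep], cc2[keep]] = (101.0, 72.0, 38.0)
    present = np.unique(labels)
    present = present[present > 0]
    # per-leaf color draws consume the photometry stream in leaf-id order,
    # independent of which leaves are visible this frame
    colors = {s.leaf_id: (prng.uniform(42, 72), prng.uniform(125, 155), prng.uniform(45, 78))
              for s in sites}
    for lid in present:
        image[labels == lid] = colors[int(lid)]
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    # ---- ground truth ----
    calib = scene_calibration(spec)
    factor = float(calib.dx * calib.dy)
    counts = np.bincount(labels.ravel(), minlength=int(labels.max()) + 1)
    true_px = {int(l): int(counts[l]) for l in present}
    true_cm2 = {k: v * factor for k, v in true_px.items()}
    annotations = []
    for lid in present:
        ann = _polygon_from_instance(labels == lid, h, w)
        if ann is not None:
            annotations.append(ann)
    return Scene(time_h=_time_h, image=image, labels=labels,
                 annotations=annotations, true_areas_px=true_px,
                 true_areas_cm2=true_cm2)


def grow_series(spec: SceneSpec, profiles: Sequence[GrowthProfile],
                times_h: Sequence[float]) -> List[Scene]:
    """Render a time series of scenes following per-leaf logistic growth.

    Leaf identities persist across frames; centroids jitter by at most
    ~1.5 px frame-to-frame to emulate slight seedling motion.
    """
    if len(profiles) != spec.n_leaves:
        raise ValueError(f"need {spec.n_leaves} profiles, got {len(profiles)}")
    calib = scene_calibration(spec)
    px_per_cm2 = 1.0 / float(calib.dx * calib.dy)
    sites = _layout(spec)
    # anchor each leaf at the offset of its largest rendered size so
    # growth changes the area, not the centroid
    offsets = []
    for site, p in zip(sites, profiles):
        peak_px = max(logistic_area(p, t) for t in times_h) * px_per_cm2
        a_peak = math.sqrt(max(peak_px, float(MIN_RENDER_AREA_PX)) /
                           (math.pi * _LOBE_RATIO * 1.55))
        offsets.append(_pair_offset(a_peak, site.overlapping))
    frames = []
    for f_idx, t in enumerate(times_h):
        frame_rng = _rng(spec.seed, 16 + f_idx)
        jitter = frame_rng.uniform(-1.5, 1.5, size=(spec.n_leaves, 2))
        areas = [logistic_area(p, t) * px_per_cm2 for p in profiles]
        frames.append(render_scene(spec, areas, _jitter=jitter, _time_h=float(t),
                                   _fixed_offsets=offsets))
    return frames


def _rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    from skimage import color
    return color.rgb2hsv(img)


def _hsv_to_rgb(img: np.ndarray) -> np.ndarray:
    from skimage import color
    return color.hsv2rgb(img)


def augment(image: np.ndarray, aug: AugmentationSpec) -> np.ndarray:
    """Apply the enabled photometric perturbations (see
    :class:`AugmentationSpec` for the fixed order).  Deterministic for a
    fixed ``aug.seed``; the input image is never modified in place."""
    aug.validate()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("augment expects an HxWx3 color image")
    out = img.astype(np.float64) / 255.0
    if aug.gamma is not None:
        out = np.power(out, aug.gamma)
    if aug.gain is not None:
        out = out * aug.gain
    out = np.clip(out, 0.0, 1.0)
    if aug.hue_shift is not None or aug.sat_scale is not None:
        hsv = _rgb_to_hsv(out)
        if aug.hue_shift is not None:
            hsv[..., 0] = np.mod(hsv[..., 0] + aug.hue_shift, 1.0)
        if aug.sat_scale is not None:
            hsv[..., 1] = np.clip(hsv[..., 1] * aug.sat_scale, 0.0, 1.0)
        out = _hsv_to_rgb(hsv)
    if aug.grayscale:
        lum = 0.2126 * out[..., 0] + 0.7152 * out[..., 1] + 0.0722 * out[..., 2]
        out = np.repeat(lum[..., None], 3, axis=2)
    if aug.blur_sigma is not None and aug.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, (aug.blur_sigma, aug.blur_sigma, 0))
    if aug.motion_blur_len is not None and aug.motion_blur_len > 1:
        out = ndimage.uniform_filter1d(out, aug.motion_blur_len, axis=1)
    if aug.noise_sigma is not None and aug.noise_sigma > 0:
        rng = np.random.default_rng(aug.seed)
        out = out + rng.normal(0.0, aug.noise_sigma, size=out.shape)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
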