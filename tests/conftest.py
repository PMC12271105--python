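"""Shared fixtures and independent brute-force oracles.

The oracles implement the defining formulas directly (double loops,
exhaustive scans, nearest-background minimization) and are kept free of
any code path they are used to check.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from seedleaf.synthdata import SceneSpec, render_scene, scene_calibration


# ---------------------------------------------------------------------------
# oracles

def brute_minmax(img, offsets, take_max, padding="ignore"):
    """Direct double-loop evaluation of the erosion/dilation definition."""
    arr = np.asarray(img, dtype=float)
    h, w = arr.shape
    out = np.empty((h, w))
    op = max if take_max else min
    for r in range(h):
        for c in range(w):
            vals = []
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    vals.append(arr[rr, cc])
                elif padding == "zero":
                    vals.append(0.0)
            out[r, c] = op(vals) if vals else arr[r, c]
    return out


def brute_otsu(img):
    """Exhaustive between-class-variance scan; smallest maximizing t."""
    vals = np.asarray(img).ravel().astype(float)
    best_sb, best_t = -1.0, None
    for t in range(int(vals.max()) + 1):
        c0 = vals[vals <= t]
        c1 = vals[vals > t]
        if len(c0) == 0 or len(c1) == 0:
            continue
        w0 = len(c0) / len(vals)
        sb = w0 * (1 - w0) * (c0.mean() - c1.mean()) ** 2
        if sb > best_sb + 1e-12:
            best_sb, best_t = sb, t
    return best_t


def brute_edt(mask):
    """Per-pixel minimization over all background pixels."""
    m = np.asarray(mask) > 0
    bg = np.argwhere(~m)
    pts = np.indices(m.shape).reshape(2, -1).T
    d = cdist(pts, bg).min(axis=1).reshape(m.shape)
    d[~m] = 0.0
    return d


def random_binary_masks(n, shape=(16, 16), p=0.5, seed=0):
    rng = np.random.default_rng(seed)
    return [(rng.random(shape) > p).astype(np.uint8) for _ in range(n)]


# ---------------------------------------------------------------------------
# synthetic scenes (small trays, module-scoped: rendering dominates runtime)

# Leaf areas match the full-assay pixel scale (0.8 cm^2 at the 25 cm /
# 1500 px calibration is ~2880 px), so morphology behaves as at tray scale.
_LEAF_AREA_PX = 2880.0


@pytest.fixture(scope="session")
def small_scene():
    """2x2 seed grid, 500 px tray, disjoint cotyledon pairs (8 leaves)."""
    spec = SceneSpec(tray_px=(500, 500), tray_cm=(10.0, 10.0), grid=(2, 2),
                     overlap_fraction=0.0, seed=11)
    scene = render_scene(spec, [_LEAF_AREA_PX] * spec.n_leaves)
    return spec, scene


@pytest.fixture(scope="session")
def overlap_scene():
    """Same tray but every cotyledon pair barely touching."""
    spec = SceneSpec(tray_px=(500, 500), tray_cm=(10.0, 10.0), grid=(2, 2),
                     overlap_fraction=1.0, seed=11)
    scene = render_scene(spec, [_LEAF_AREA_PX] * spec.n_leaves)
    return spec, scene


@pytest.fixture(scope="session")
def small_calibration(small_scene):
    spec, _ = small_scene
    return scene_calibration(spec)
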