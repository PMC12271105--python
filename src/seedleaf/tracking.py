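"""Link per-frame leaf instances into tracks and derive growth rates.

Germinating seedlings are near-stationary, so association is greedy
nearest-centroid matching between consecutive frames, gated by a maximum
displacement; ties break on larger bounding-box overlap, then lower
instance id.  A track that misses a frame ends — leaves do not merge or
swap identities in this assay, and no id is ever reused.

The relative growth rate (RGR) of a track is the percent change in area
between consecutive observations,

    rgr_k = 100 * (A_k - A_{k-1}) / A_{k-1},

reported per sampling interval by default, with an optional per-hour
normalization.  RGR is a ratio of areas and therefore identical whether
computed on pixel or physical areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pipeline import FrameResult
from .quantify import LeafMeasurement

__all__ = [
    "TrackingConfig",
    "LeafTrack",
    "link_frames",
    "relative_growth_rate",
    "growth_summary",
    "tracks_long_table",
    "write_tracks_csv",
    "plot_growth_curves",
]


@dataclass(frozen=True)
class TrackingConfig:
    max_displacement: float = 30.0   # px; seedlings barely move at tray scale
    min_track_length: int = 1        # frames; tracks shorter than this are dropped
    interval_h: float = 0.25         # nominal 15-minute capture cadence
    per_hour: bool = False           # normalize RGR to the nominal interval per hour

    def __post_init__(self):
        if self.max_displacement <= 0 or self.interval_h <= 0:
            raise ValueError("max_displacement and interval_h must be positive")


@dataclass
class LeafTrack:
    """One leaf's time-ordered observations and derived growth rates.

    ``rgr`` holds one ``(time_h, pct)`` pair per consecutive observation
    pair, timestamped at the interval end; an interval whose preceding
    area is zero carries ``nan`` (flagged, never dropped).
    """

    leaf_id: int
    observations: List[Tuple[float, LeafMeasurement]] = field(default_factory=list)
    rgr: List[Tuple[float, float]] = field(default_factory=list)

    @property
    def times(self) -> List[float]:
        return [t for t, _ in self.observations]

    @property
    def areas_px(self) -> List[int]:
        return [m.area_px for _, m in self.observations]

    @property
    def areas_cm2(self) -> List[float]:
        return [m.area_cm2 for _, m in self.observations]


def _bbox_overlap(a, b) -> float:
    r0 = max(a[0], b[0]); c0 = max(a[1], b[1])
    r1 = min(a[2], b[2]); c1 = min(a[3], b[3])
    return max(0, r1 - r0) * max(0, c1 - c0)


def link_frames(frames: Sequence[FrameResult],
                cfg: Optional[TrackingConfig] = None) -> List[LeafTrack]:
    """Associate detections across a time-ordered frame sequence.

    Candidate (track, detection) pairs within ``max_displacement`` px are
    assigned greedily by increasing centroid distance (ties: larger bbox
    overlap, then lower instance id).  Unmatched detections open new
    tracks; a track unmatched in a frame is closed for good.  Tracks
    shorter than ``min_track_length`` are dropped, and every surviving
    track gets its RGR series.
    """
    cfg = cfg or TrackingConfig()
    times = [f.time_h for f in frames]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("frames must be strictly time-ordered")
    finished: List[LeafTrack] = []
    active: List[LeafTrack] = []
    next_id = 1
    for frame in frames:
        dets = frame.measurements
        candidates = []
        for ti, track in enumerate(active):
            last = track.observations[-1][1]
            for det in dets:
                d = math.hypot(det.centroid[0] - last.centroid[0],
                               det.centroid[1] - last.centroid[1])
                if d <= cfg.max_displacement:
                    candidates.append((d, -_bbox_overlap(det.bbox, last.bbox),
                                       det.instance_id, ti, det))
        candidates.sort(key=lambda c: c[:3])
        used_tracks, used_dets = set(), set()
        for d, _, inst, ti, det in candidates:
            if ti in used_tracks or inst in used_dets:
                continue
            active[ti].observations.append((frame.time_h, det))
            used_tracks.add(ti)
            used_dets.add(inst)
        # tracks that found no detection this frame terminate
        still_active = []
        for ti, track in enumerate(active):
            (still_active if ti in used_tracks else finished).append(track)
        active = still_active
        for det in dets:
            if det.instance_id not in used_dets:
                t = LeafTrack(leaf_id=next_id, observations=[(frame.time_h, det)])
                next_id += 1
                active.append(t)
    finished.extend(active)
    finished.sort(key=lambda t: t.leaf_id)
    kept = [t for t in finished if len(t.observations) >= (cfg.min_track_length or 1)]
    for t in kept:
        if len(t.observations) >= 2:
            relative_growth_rate(t, per_hour=cfg.per_hour, interval_h=cfg.interval_h)
    return kept


def relative_growth_rate(track: LeafTrack, per_hour: bool = False,
                         interval_h: float = 1.0) -> LeafTrack:
    """Fill ``track.rgr`` with percent area change per interval.

    With ``per_hour=True`` each entry is rescaled by
    ``interval_h / (t_k - t_{k-1})`` so rates are comparable across
    uneven sampling.  Requires at least two observations.
    """
    if len(track.observations) < 2:
        raise ValueError("relative growth rate needs >= 2 observations")
    rgr: List[Tuple[float, float]] = []
    for (t0, m0), (t1, m1) in zip(track.observations, track.observations[1:]):
        if m0.area_px <= 0:
            rgr.append((t1, float("nan")))  # undefined interval, flagged
            continue
        pct = 100.0 * (m1.area_px - m0.area_px) / m0.area_px
        if per_hour:
            pct *= interval_h / (t1 - t0)
        rgr.append((t1, pct))
    track.rgr = rgr
    return track


def growth_summary(tracks: Sequence[LeafTrack]) -> pd.DataFrame:
    """Per-leaf growth synopsis: initial/final area, peak RGR and its
    time, and the fraction of strictly increasing area steps."""
    rows = []
    for t in tracks:
        areas = t.areas_cm2
        rates = [(tt, v) for tt, v in t.rgr if not math.isnan(v)]
        peak = max(rates, key=lambda x: x[1]) if rates else (float("nan"), float("nan"))
        steps = [b > a for a, b in zip(areas, areas[1:])]
        rows.append({
            "leaf_id": t.leaf_id,
            "n_obs": len(t.observations),
            "t_start_h": t.times[0],
            "t_end_h": t.times[-1],
            "area_initial_cm2": areas[0],
            "area_final_cm2": areas[-1],
            "peak_rgr_pct": peak[1],
            "peak_rgr_time_h": peak[0],
            "monotonic_fraction": (sum(steps) / len(steps)) if steps else float("nan"),
        })
    return pd.DataFrame(rows, columns=[
        "leaf_id", "n_obs", "t_start_h", "t_end_h", "area_initial_cm2",
        "area_final_cm2", "peak_rgr_pct", "peak_rgr_time_h", "monotonic_fraction"])


def tracks_long_table(tracks: Sequence[LeafTrack]) -> pd.DataFrame:
    """Long-format (leaf_id, time_h, area_px, area_cm2, rgr_pct) table
    for plotting area-vs-time and rgr-vs-time."""
    rows = []
    for t in tracks:
        rgr_by_time = dict(t.rgr)
        for time_h, m in t.observations:
            rows.append({
                "leaf_id": t.leaf_id,
                "time_h": time_h,
                "area_px": m.area_px,
                "area_cm2": m.area_cm2,
                "rgr_pct": rgr_by_time.get(time_h, float("nan")),
            })
    return pd.DataFrame(rows, columns=["leaf_id", "time_h", "area_px", "area_cm2", "rgr_pct"])


def write_tracks_csv(path, tracks: Sequence[LeafTrack]) -> pd.DataFrame:
    df = tracks_long_table(tracks)
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def plot_growth_curves(tracks: Sequence[LeafTrack], path):
    """Area-vs-time and RGR-vs-time panels, one line per leaf (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for t in tracks:
        ax1.plot(t.times, t.areas_cm2, marker="o", ms=3, label=f"leaf {t.leaf_id}")
        if t.rgr:
            ax2.plot([x for x, _ in t.rgr], [y for _, y in t.rgr], marker="o", ms=3)
    ax1.set_xlabel("time (h)"); ax1.set_ylabel("leaf area (cm$^2$)")
    ax2.set_xlabel("time (h)"); ax2.set_ylabel("RGR (% per interval)")
    if tracks:
        ax1.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
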