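"""Nucleus tracking across time-lapse frames and group statistics.

Linking is deterministic greedy nearest-neighbour matching on centroids:
candidate pairs between consecutive frames are sorted by ascending
distance and accepted one-to-one while the displacement stays within
``max_disp_px`` (default 30 px, adequate for slow-moving adherent
cells).  Unmatched objects open new tracks; tracks shorter than
``min_len`` are discarded.  A track keeps one identity through a
live->dead transition; the class is recorded per timepoint.

Morphology readouts follow the dry-mass convention of the optics module
(area = pixel count x pixel size^2; mass = integrated phase over the
object mask) and trajectories are normalised to their value at t = 0.
Group comparisons use a two-sided Welch t-test per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import NucleusRecord, extract_objects
from .ground_truth import SemanticMap
from .optics import OpticsConfig, PhaseMap, compute_dry_mass


@dataclass
class TrackPoint:
    frame: int
    nucleus: NucleusRecord
    area_um2: float | None = None
    dry_mass_pg: float | None = None


@dataclass
class Track:
    track_id: int
    points: list[TrackPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [p.frame for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> list[int]:
        return [p.frame for p in self.points]


def link_tracks(frames: list[SemanticMap], max_disp_px: float = 30.0,
                min_len: int = 5, min_area_px: int = 50) -> list[Track]:
    """Link per-frame nuclei into tracks by greedy nearest-neighbour matching."""
    if len(frames) == 0:
        raise ValueError("empty frame list")
    per_frame = [extract_objects(f, min_area_px) for f in frames]

    open_tracks: list[Track] = []
    finished: list[Track] = []
    next_id = 1
    for obj in per_frame[0]:
        open_tracks.append(Track(next_id, [TrackPoint(0, obj)]))
        next_id += 1

    for f in range(1, len(frames)):
        objs = per_frame[f]
        # candidate pairs (distance, track index, object index), greedy 1-1
        pairs = []
        for ti, tr in enumerate(open_tracks):
            cy, cx = tr.points[-1].nucleus.centroid
            for oi, obj in enumerate(objs):
                d = float(np.hypot(obj.centroid[0] - cy, obj.centroid[1] - cx))
                if d <= max_disp_px:
                    pairs.append((d, ti, oi))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_t, used_o = set(), set()
        for d, ti, oi in pairs:
            if ti in used_t or oi in used_o:
                continue
            used_t.add(ti)
            used_o.add(oi)
            open_tracks[ti].points.append(TrackPoint(f, objs[oi]))
        still_open = []
        for ti, tr in enumerate(open_tracks):
            if ti in used_t:
                still_open.append(tr)
            else:
                finished.append(tr)
        for oi, obj in enumerate(objs):
            if oi not in used_o:
                still_open.append(Track(next_id, [TrackPoint(f, obj)]))
                next_id += 1
        open_tracks = still_open

    finished.extend(open_tracks)
    kept = [t for t in finished if len(t) >= min_len]
    kept.sort(key=lambda t: t.track_id)
    for new_id, t in enumerate(kept, start=1):
        t.track_id = new_id
    return kept


def measure_track(track: Track, phases: list[PhaseMap], maps: list[SemanticMap],
                  cfg: OpticsConfig = OpticsConfig()) -> Track:
    """Fill per-timepoint physical area (um^2) and dry mass (pg)."""
    for pt in track.points:
        if pt.frame >= len(phases) or pt.frame >= len(maps):
            raise IndexError(f"track frame {pt.frame} outside the frame lists")
        pm = phases[pt.frame]
        mask = pt.nucleus.mask(maps[pt.frame].shape)
        pt.area_um2 = float(pt.nucleus.area_px) * pm.pixel_size_um**2
        pt.dry_mass_pg = compute_dry_mass(pm, mask, cfg)
    return track


def normalize_series(values) -> np.ndarray:
    """Divide a series by its first element (relative change vs t = 0)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if values[0] == 0:
        raise ZeroDivisionError("series starts at 0; cannot normalize")
    return values / values[0]


def track_series(track: Track, quantity: str) -> np.ndarray:
    attr = {"area": "area_um2", "mass": "dry_mass_pg"}[quantity]
    vals = [getattr(p, attr) for p in track.points]
    if any(v is None for v in vals):
        raise ValueError("track has unmeasured points; run measure_track first")
    return normalize_series(vals)


def group_stats(group_a: list[Track], group_b: list[Track],
                quantity: str = "area") -> pd.DataFrame:
    """Per-timepoint mean, SEM and Welch t-test between two track groups.

    Tracks are aligned by position within each track (relative time
    since its first frame); the quantity is the normalised series, so
    every track contributes exactly 1.0 at its first timepoint.  Requires
    at least two tracks per group at every compared timepoint.
    """
    sa = [track_series(t, quantity) for t in group_a]
    sb = [track_series(t, quantity) for t in group_b]
    n_t = min(max((len(s) for s in sa), default=0),
              max((len(s) for s in sb), default=0))
    rows = []
    for t in range(n_t):
        va = np.array([s[t] for s in sa if len(s) > t])
        vb = np.array([s[t] for s in sb if len(s) > t])
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(f"fewer than 2 tracks in a group at timepoint {t}")
        if va.var(ddof=1) == 0.0 and vb.var(ddof=1) == 0.0:
            # degenerate but well-defined: e.g. every normalised series is
            # exactly 1.0 at t = 0
            equal = va.mean() == vb.mean()
            t_stat, p_val = (0.0, 1.0) if equal else (np.inf, 0.0)
        else:
            tt = stats.ttest_ind(va, vb, equal_var=False)
            t_stat, p_val = float(tt.statistic), float(tt.pvalue)
        rows.append({
            "timepoint": t,
            "mean_a": va.mean(), "sem_a": va.std(ddof=1) / np.sqrt(len(va)),
            "n_a": len(va),
            "mean_b": vb.mean(), "sem_b": vb.std(ddof=1) / np.sqrt(len(vb)),
            "n_b": len(vb),
            "t_stat": t_stat, "welch_p": p_val,
        })
    return pd.DataFrame(rows)


def tracks_table(tracks: list[Track], frame_interval_min: float = 30.0,
                 classes_known: bool = True) -> pd.DataFrame:
    """Flatten tracks to the CSV schema (one row per track-timepoint)."""
    rows = []
    for tr in tracks:
        for p in tr.points:
            rows.append({
                "track_id": tr.track_id,
                "frame": p.frame,
                "t_hours": p.frame * frame_interval_min / 60.0,
                "centroid_row": p.nucleus.centroid[0],
                "centroid_col": p.nucleus.centroid[1],
                "area_px": p.nucleus.area_px,
                "area_um2": p.area_um2,
                "dry_mass_pg": p.dry_mass_pg,
                "class": {0: "live", 1: "dead"}[p.nucleus.cls],
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_hours",
                                       "centroid_row", "centroid_col",
                                       "area_px", "area_um2", "dry_mass_pg",
                                       "class"])
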