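"""3D centroid tracking and velocity statistics.

Per-frame cell objects are linked into tracks by greedy mutual-nearest-
neighbor assignment between consecutive frames, with single-frame gap
closing.  Velocities are forward differences of the 3D centroid positions
divided by the frame interval — no smoothing by default, because the
correctness standard here is recovery of programmed speeds on synthetic
scenes (a central-difference option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import CellObject

__all__ = [
    "Track",
    "CohortVelocity",
    "link_tracks",
    "velocity_stats",
    "compare_cohorts",
    "tracks_to_table",
]

#: Default maximum link length, ~3 μm/min over a 10-min frame interval.
DEFAULT_MAX_STEP_UM = 30.0

#: Minimum track length (frames) for cohort statistics; single-step speeds
#: are noise-dominated.
MIN_TRACK_FRAMES = 6


@dataclass
class Track:
    """One cell's 3D centroid path over time."""

    track_id: int
    times_min: list[float] = field(default_factory=list)
    centroids_um: list[np.ndarray] = field(default_factory=list)
    objects: list[CellObject] = field(default_factory=list)

    def append(self, time_min: float, obj: CellObject) -> None:
        if self.times_min and time_min <= self.times_min[-1]:
            raise ValueError("track times must be strictly increasing")
        self.times_min.append(time_min)
        self.centroids_um.append(np.asarray(obj.centroid_um, dtype=float))
        self.objects.append(obj)

    def __len__(self) -> int:
        return len(self.times_min)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray(self.centroids_um).reshape(len(self), 3)

    @property
    def path_length_um(self) -> float:
        p = self.positions
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum()) if len(p) > 1 else 0.0

    @property
    def net_displacement_um(self) -> float:
        p = self.positions
        return float(np.linalg.norm(p[-1] - p[0])) if len(p) > 1 else 0.0

    @property
    def persistence(self) -> float:
        """Net displacement over path length, in [0, 1] (1 for a stationary track)."""
        length = self.path_length_um
        return self.net_displacement_um / length if length > 0 else 1.0

    @property
    def mean_speed_um_min(self) -> float:
        """Path length over elapsed time, μm/min."""
        if len(self) < 2:
            raise ValueError("mean speed undefined for a single-point track")
        elapsed = self.times_min[-1] - self.times_min[0]
        return self.path_length_um / elapsed


def velocity_stats(track: Track, scheme: str = "forward"):
    """Per-step speeds (μm/min) and summary statistics of one track.

    ``forward``: ``speed_i = |c_{i+1} - c_i| / (t_{i+1} - t_i)``, one value
    per inter-frame step, attributed to frame ``i``.  ``central`` averages
    positions over a 3-frame window before differencing.
    Returns ``(mean_speed, speeds, persistence)``.
    """
    if len(track) < 2:
        raise ValueError("velocity undefined for a single-point track")
    p = track.positions
    t = np.asarray(track.times_min)
    if scheme == "forward":
        speeds = np.linalg.norm(np.diff(p, axis=0), axis=1) / np.diff(t)
    elif scheme == "central":
        if len(track) < 3:
            speeds = np.linalg.norm(np.diff(p, axis=0), axis=1) / np.diff(t)
        else:
            speeds = np.linalg.norm(p[2:] - p[:-2], axis=1) / (t[2:] - t[:-2])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return track.mean_speed_um_min, speeds, track.persistence


def _mutual_nearest(prev_pts: np.ndarray, new_pts: np.ndarray, max_step: float):
    """Greedy mutual-nearest-neighbor pairs under the step bound."""
    if len(prev_pts) == 0 or len(new_pts) == 0:
        return []
    d = np.linalg.norm(prev_pts[:, None, :] - new_pts[None, :, :], axis=2)
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    order = np.argsort(d, axis=None, kind="stable")
    for flat in order:
        a, b = np.unravel_index(flat, d.shape)
        if d[a, b] > max_step:
            break
        if a in used_a or b in used_b:
            continue
        # mutual nearest among unused candidates
        if any(d[a, bb] < d[a, b] for bb in range(len(new_pts)) if bb not in used_b):
            continue
        if any(d[aa, b] < d[a, b] for aa in range(len(prev_pts)) if aa not in used_a):
            continue
        pairs.append((int(a), int(b)))
        used_a.add(int(a))
        used_b.add(int(b))
    return pairs


def link_tracks(
    frames: list[list[CellObject]],
    times_min: list[float] | np.ndarray,
    max_step_um: float = DEFAULT_MAX_STEP_UM,
    gap_closing: bool = True,
) -> list[Track]:
    """Link per-frame cell objects into tracks.

    Objects in consecutive frames are paired greedily by mutual nearest
    neighbors, never over a step longer than ``max_step_um``; unmatched
    objects seed new tracks.  A track missing exactly one frame may be
    reconnected (gap closing) at the same step bound.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames to link")
    times = list(map(float, times_min))
    tracks: list[Track] = []
    open_tracks: list[tuple[Track, int]] = []  # (track, last frame index)
    for obj in frames[0]:
        tr = Track(track_id=len(tracks))
        tr.append(times[0], obj)
        tracks.append(tr)
        open_tracks.append((tr, 0))
    for fi in range(1, len(frames)):
        objs = frames[fi]
        new_pts = np.array([o.centroid_um for o in objs]).reshape(len(objs), 3)
        assigned = [False] * len(objs)
        for lag in (1, 2):
            if lag == 2 and not gap_closing:
                break
            cands = [(k, tr) for k, (tr, last) in enumerate(open_tracks) if last == fi - lag]
            if not cands:
                continue
            free = [b for b in range(len(objs)) if not assigned[b]]
            if not free:
                break
            prev_pts = np.array([tr.positions[-1] for _, tr in cands]).reshape(len(cands), 3)
            for a, b_free in _mutual_nearest(prev_pts, new_pts[free], max_step_um):
                k, tr = cands[a]
                b = free[b_free]
                tr.append(times[fi], objs[b])
                open_tracks[k] = (tr, fi)
                assigned[b] = True
        for b, obj in enumerate(objs):
            if not assigned[b]:
                tr = Track(track_id=len(tracks))
                tr.append(times[fi], obj)
                tracks.append(tr)
                open_tracks.append((tr, fi))
        open_tracks = [(tr, last) for tr, last in open_tracks if last >= fi - 1]
    return tracks


@dataclass
class CohortVelocity:
    """Mean ± SD of per-track mean speeds of one track cohort."""

    label: str
    n: int
    mean_um_min: float
    sd_um_min: float
    comparisons: list[dict] = field(default_factory=list)


def compare_cohorts(
    tracks_a: list[Track],
    tracks_b: list[Track],
    label_a: str = "A",
    label_b: str = "B",
    welch: bool = False,
    min_frames: int = MIN_TRACK_FRAMES,
    persistence_min: float | None = None,
) -> tuple[CohortVelocity, CohortVelocity]:
    """Two-sample t-test on per-track mean speeds of two cohorts.

    Pooled-variance Student's t by default (Welch optional).  The percent
    change of the means is reported as ``100 * (1 - mean_b / mean_a)``.
    Tracks shorter than ``min_frames`` are excluded; an optional
    ``persistence_min`` filter restricts to persistently translocating
    cells.
    """

    def speeds(tracks):
        vals = []
        for tr in tracks:
            if len(tr) < min_frames:
                continue
            if persistence_min is not None and tr.persistence < persistence_min:
                continue
            vals.append(tr.mean_speed_um_min)
        return np.asarray(vals)

    sa, sb = speeds(tracks_a), speeds(tracks_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each cohort needs at least two usable tracks")
    if np.ptp(sa) == 0 and np.ptp(sb) == 0 and sa[0] == sb[0]:
        p_value, t_stat = 1.0, 0.0  # identical degenerate samples
    else:
        t_stat, p_value = stats.ttest_ind(sa, sb, equal_var=not welch)
    mean_a, mean_b = float(sa.mean()), float(sb.mean())
    comp = {
        "other": label_b,
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "test": "welch-t" if welch else "student-t",
        "percent_change": 100.0 * (1.0 - mean_b / mean_a) if mean_a else np.nan,
    }
    cohort_a = CohortVelocity(label_a, len(sa), mean_a, float(sa.std(ddof=1)), [comp])
    cohort_b = CohortVelocity(label_b, len(sb), mean_b, float(sb.std(ddof=1)))
    return cohort_a, cohort_b


def tracks_to_table(tracks: list[Track], states: dict[int, list[str]] | None = None) -> pd.DataFrame:
    """Flatten tracks into the on-disk track-table layout (io.TRACK_COLUMNS)."""
    rows = []
    for tr in tracks:
        labels = states.get(tr.track_id) if states else None
        for i, (t, c, obj) in enumerate(zip(tr.times_min, tr.centroids_um, tr.objects)):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "time_min": t,
                    "x_um": c[2],
                    "y_um": c[1],
                    "z_um": c[0],
                    "state_label": labels[i] if labels else "FREE",
                    "cell_voxel_count": obj.voxel_count,
                }
            )
    return pd.DataFrame(rows, columns=[
        "track_id", "time_min", "x_um", "y_um", "z_um", "state_label", "cell_voxel_count",
    ])
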