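"""Behavioral state classification of tracked cells relative to the network.

Each tracked cell is labeled per frame as FREE, APPROACHING (free but
closing on the network), ON_NETWORK (in surface contact) or INSIDE_NETWORK
(majority of the body voxels overlapping the network mass — the
majority-inside rule), and per-track events are extracted: first CONTACT,
ADHESION (persistent contact), DETACH, and ENTER/EXIT pairs bounding
penetration episodes.  Population summaries bin tracks by their initial
cell-surface-to-network-surface distance, mirroring the near (≤65 μm) and
far (≥80 μm) cohorts used when scoring which cells translocate to and
adhere to a network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import BinaryVolume, CellObject
from .tracking import Track, velocity_stats

__all__ = [
    "BehaviorParams",
    "AnnotatedTrack",
    "classify_frame",
    "annotate_track",
    "annotate_tracks",
    "population_summary",
]

EVENT_COLUMNS = ["track_id", "event", "time_min"]
CONTACT_STATES = ("ON_NETWORK", "INSIDE_NETWORK")


@dataclass(frozen=True)
class BehaviorParams:
    """Thresholds of the behavioral state machine.

    ``d_contact_um`` — surface-to-surface contact distance (default: one
    lateral voxel, i.e. adjacency).  ``inside_fraction`` — the
    majority-inside rule: a cell whose overlap fraction reaches this value
    is INSIDE_NETWORK (boundary inclusive).  ``near_band_um`` /
    ``far_band_um`` — initial-distance bins.  ``displacement_threshold_um``
    — a track with smaller net displacement counts as non-translocating
    (default: one 30-μm cell diameter).
    """

    d_contact_um: float | None = None
    adhesion_min_frames: int = 3
    inside_fraction: float = 0.5
    near_band_um: float = 65.0
    far_band_um: float = 80.0
    detach_min_frames: int = 3
    approach_tolerance_um: float = 2.0
    displacement_threshold_um: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 < self.inside_fraction <= 1.0):
            raise ValueError("inside_fraction must lie in (0, 1]")
        if self.near_band_um >= self.far_band_um:
            raise ValueError("near band must lie below far band")
        for name in ("adhesion_min_frames", "detach_min_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def contact_distance(self, mask: BinaryVolume) -> float:
        if self.d_contact_um is not None:
            return self.d_contact_um
        return max(mask.calibration.dx_um, mask.calibration.dy_um)


def network_edt(mask: BinaryVolume) -> np.ndarray:
    """Anisotropy-aware distance (μm) to the nearest network voxel."""
    return ndimage.distance_transform_edt(~mask.mask, sampling=mask.calibration.spacing)


def classify_frame(
    cell: CellObject,
    mask: BinaryVolume,
    params: BehaviorParams | None = None,
    edt: np.ndarray | None = None,
) -> tuple[str, float, float]:
    """Classify one cell against one network mask.

    Returns ``(state, distance_um, inside_fraction)`` where the distance is
    the minimum anisotropy-aware Euclidean distance from any cell voxel to
    the network (0 when overlapping) and the inside fraction is
    ``|cell ∩ network| / |cell|``.  APPROACHING is a track-level refinement
    and is never returned here.  An empty network mask yields FREE with an
    infinite distance.
    """
    if params is None:
        params = BehaviorParams()
    if not mask.mask.any():
        return "FREE", math.inf, 0.0
    vz, vy, vx = cell.voxels.T
    overlap = mask.mask[vz, vy, vx]
    f = float(overlap.mean())
    if f > 0:
        distance = 0.0
    else:
        if edt is None:
            edt = network_edt(mask)
        distance = float(edt[vz, vy, vx].min())
    if f >= params.inside_fraction:
        return "INSIDE_NETWORK", distance, f
    if distance <= params.contact_distance(mask):
        return "ON_NETWORK", distance, f
    return "FREE", distance, f


@dataclass
class AnnotatedTrack:
    """A track with per-frame states, distances and extracted events."""

    track: Track
    states: list[str]
    distances_um: list[float]
    inside_fractions: list[float]
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    @property
    def initial_distance_um(self) -> float:
        return self.distances_um[0]

    def has_event(self, name: str) -> bool:
        return bool((self.events["event"] == name).any())


def annotate_track(
    track: Track,
    frame_states: list[str],
    distances_um: list[float],
    params: BehaviorParams | None = None,
    inside_fractions: list[float] | None = None,
) -> AnnotatedTrack:
    """Refine per-frame labels into the track-level state sequence + events.

    FREE frames that belong to a monotone (within ``approach_tolerance_um``)
    distance descent over a 3-frame window, on a track that eventually makes
    contact, are relabeled APPROACHING.  Events: CONTACT at the first
    contact frame; ADHESION when contact has persisted
    ``adhesion_min_frames`` frames; DETACH when an adhered cell has been
    free again for ``detach_min_frames`` frames; ENTER/EXIT at the
    boundaries of INSIDE_NETWORK episodes.
    """
    if params is None:
        params = BehaviorParams()
    n = len(track)
    if not (len(frame_states) == len(distances_um) == n):
        raise ValueError("labels/distances must align with the track")
    states = list(frame_states)
    contact_idx = [i for i, s in enumerate(states) if s in CONTACT_STATES]
    first_contact = contact_idx[0] if contact_idx else None
    tol = params.approach_tolerance_um
    if first_contact is not None:
        for i in range(first_contact):
            if states[i] != "FREE":
                continue
            window = distances_um[i : min(i + 3, first_contact + 1)]
            if len(window) >= 2 and all(
                b <= a + tol for a, b in zip(window, window[1:])
            ):
                states[i] = "APPROACHING"

    events = []
    times = track.times_min
    if first_contact is not None:
        events.append((track.track_id, "CONTACT", times[first_contact]))
    # adhesion / detachment
    adhered = False
    run = 0
    free_run = 0
    for i, s in enumerate(states):
        if s in CONTACT_STATES:
            run += 1
            free_run = 0
            if not adhered and run >= params.adhesion_min_frames:
                adhered = True
                events.append((track.track_id, "ADHESION", times[i]))
        else:
            run = 0
            if adhered:
                free_run += 1
                if free_run == params.detach_min_frames:
                    adhered = False
                    events.append((track.track_id, "DETACH", times[i - free_run + 1]))
            else:
                free_run = 0
    # penetration episodes
    inside_prev = False
    for i, s in enumerate(states):
        inside = s == "INSIDE_NETWORK"
        if inside and not inside_prev:
            events.append((track.track_id, "ENTER", times[i]))
        if inside_prev and not inside:
            events.append((track.track_id, "EXIT", times[i]))
        inside_prev = inside
    ev = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return AnnotatedTrack(
        track=track,
        states=states,
        distances_um=list(distances_um),
        inside_fractions=list(inside_fractions) if inside_fractions else [np.nan] * n,
        events=ev,
    )


def annotate_tracks(
    tracks: list[Track],
    masks: list[BinaryVolume],
    times_min: list[float] | np.ndarray,
    params: BehaviorParams | None = None,
) -> list[AnnotatedTrack]:
    """Classify every track frame against the per-frame network masks."""
    if params is None:
        params = BehaviorParams()
    times = list(map(float, times_min))
    edts = {}
    time_index = {t: i for i, t in enumerate(times)}
    annotated = []
    for tr in tracks:
        labels, dists, fracs = [], [], []
        for t, obj in zip(tr.times_min, tr.objects):
            fi = time_index[t]
            mask = masks[fi]
            if fi not in edts and mask.mask.any():
                edts[fi] = network_edt(mask)
            state, d, f = classify_frame(obj, mask, params, edt=edts.get(fi))
            labels.append(state)
            dists.append(d)
            fracs.append(f)
        annotated.append(annotate_track(tr, labels, dists, params, fracs))
    return annotated


def _bin_label(d: float, params: BehaviorParams) -> str:
    if d <= params.near_band_um:
        return "near"
    if d >= params.far_band_um:
        return "far"
    return "mid"


def population_summary(
    annotated: list[AnnotatedTrack],
    params: BehaviorParams | None = None,
) -> pd.DataFrame:
    """Cohort summary per initial-distance bin.

    For each bin (near ≤ ``near_band_um``; far ≥ ``far_band_um``;
    intermediate separately): track count, fraction reaching ADHESION,
    detachment fraction among adhered, mean ± SD approach speed (over
    APPROACHING frames) and on-network speed (over ON_NETWORK frames only),
    penetration (ENTER) count, and the fraction of non-translocating tracks
    (net displacement below ``displacement_threshold_um``).  Empty bins
    report ``n=0`` with undefined (NaN) fractions rather than zeros.
    """
    if params is None:
        params = BehaviorParams()
    if not annotated:
        raise ValueError("population summary needs at least one track")
    per_bin: dict[str, dict] = {
        b: {
            "n": 0,
            "adhered": 0,
            "detached": 0,
            "approach_speeds": [],
            "on_network_speeds": [],
            "penetrations": 0,
            "nontranslocating": 0,
        }
        for b in ("near", "mid", "far")
    }
    for ann in annotated:
        b = per_bin[_bin_label(ann.initial_distance_um, params)]
        b["n"] += 1
        adhered = ann.has_event("ADHESION")
        b["adhered"] += adhered
        if adhered:
            b["detached"] += ann.has_event("DETACH")
        b["penetrations"] += int((ann.events["event"] == "ENTER").sum())
        if ann.track.net_displacement_um < params.displacement_threshold_um:
            b["nontranslocating"] += 1
        if len(ann.track) >= 2:
            _, speeds, _ = velocity_stats(ann.track)
            for i, s in enumerate(ann.states[:-1]):
                if s == "APPROACHING":
                    b["approach_speeds"].append(speeds[i])
                elif s == "ON_NETWORK":
                    b["on_network_speeds"].append(speeds[i])
    rows = []
    for name, b in per_bin.items():
        n = b["n"]
        app = np.asarray(b["approach_speeds"])
        on = np.asarray(b["on_network_speeds"])
        rows.append(
            {
                "bin": name,
                "n": n,
                "adhered_fraction": b["adhered"] / n if n else np.nan,
                "detach_fraction": b["detached"] / b["adhered"] if b["adhered"] else np.nan,
                "approach_speed_mean": app.mean() if app.size else np.nan,
                "approach_speed_sd": app.std(ddof=1) if app.size > 1 else np.nan,
                "on_network_speed_mean": on.mean() if on.size else np.nan,
                "on_network_speed_sd": on.std(ddof=1) if on.size > 1 else np.nan,
                "penetration_events": b["penetrations"],
                "nontranslocating_fraction": b["nontranslocating"] / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
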