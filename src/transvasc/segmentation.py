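"""Per-frame segmentation: gap-preserving network masks and cell objects.

The endothelial channel is segmented by a plain bitmap rule — every voxel at
or above threshold is foreground, with *no* hole filling and *no*
morphological closing, so genuine gaps and spaces in the reticulated network
survive segmentation.  The cancer-cell channel is segmented by threshold
detection into 26-connected components; each component's per-section outline
is replaced by a smoothed closed B-spline contour, and its 3D centroid is
the unweighted mean of its voxel centers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .io import Calibration

__all__ = [
    "BinaryVolume",
    "CellObject",
    "SplineParams",
    "default_min_voxels",
    "segment_network",
    "segment_cells",
    "contours_to_json",
]

#: 26-connectivity structuring element for 3D component labeling.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryVolume:
    """A per-frame boolean (z, y, x) mask with its calibration."""

    mask: np.ndarray
    calibration: Calibration
    channel: str = "network"
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class SplineParams:
    """Closed uniform cubic B-spline smoothing of per-section outlines.

    ``smoothing`` is the ``splprep`` residual budget; when ``None`` it
    defaults to half the contour perimeter in pixels.  ``n_points`` is the
    resampling density per section.
    """

    smoothing: float | None = None
    n_points: int = 64


@dataclass
class CellObject:
    """A segmented cell (or touching-cell aggregate) in one frame."""

    object_id: int
    time_min: float
    voxels: np.ndarray  # (n, 3) int indices (z, y, x)
    centroid_um: np.ndarray  # (3,) physical (z, y, x)
    voxel_count: int
    contours: dict[int, np.ndarray] = field(default_factory=dict)  # z -> (m, 2) μm (y, x), closed

    @property
    def z_sections(self) -> list[int]:
        return sorted(self.contours)


def default_min_voxels(calibration: Calibration, diameter_um: float = 10.0) -> int:
    """Voxel count of a sphere of the given diameter — the debris floor.

    Objects smaller than a 10-μm sphere are far below a plausible cancer
    cell body (~30 μm) and are discarded as debris.
    """
    volume = 4.0 / 3.0 * math.pi * (diameter_um / 2.0) ** 3
    return max(1, int(round(volume / calibration.voxel_volume_um3)))


def _foreground(grid: np.ndarray, threshold_mode: str | float) -> np.ndarray | None:
    """Threshold a grid: fixed thresholds are inclusive (voxel >= t is
    foreground); Otsu follows its convention (foreground strictly above the
    returned level, which sits at the top of the background class).
    Returns None for a constant (all-background) frame."""
    if isinstance(threshold_mode, (int, float)) and not isinstance(threshold_mode, bool):
        return grid >= float(threshold_mode)
    if threshold_mode != "otsu":
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    if grid.min() == grid.max():
        return None  # constant frame: nothing to separate
    return grid > threshold_otsu(grid)


def segment_network(
    grid: np.ndarray,
    calibration: Calibration,
    threshold_mode: str | float = "otsu",
    min_component_voxels: int | None = None,
    time_min: float = 0.0,
) -> BinaryVolume:
    """Bitmap segmentation of the endothelial network channel.

    Voxels at or above the threshold (per-volume Otsu by default, or a fixed
    value) are foreground.  Components below ``min_component_voxels``
    (default: the volume of a 10-μm sphere) are removed.  Gap preservation
    is contractual: no hole filling, no closing.
    """
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("empty intensity grid")
    if min_component_voxels is None:
        min_component_voxels = default_min_voxels(calibration)
    mask = _foreground(grid, threshold_mode)
    if mask is None:
        warnings.warn("all-background network frame: returning empty mask", stacklevel=2)
        mask = np.zeros(grid.shape, dtype=bool)
    else:
        if not mask.any():
            warnings.warn("all-background network frame: returning empty mask", stacklevel=2)
        elif min_component_voxels > 1:
            labels, n = ndimage.label(mask, structure=_STRUCT_26)
            if n:
                counts = np.bincount(labels.ravel())
                keep = counts >= min_component_voxels
                keep[0] = False
                mask = keep[labels]
    return BinaryVolume(mask=mask, calibration=calibration, channel="network", time_min=time_min)


def segment_cells(
    grid: np.ndarray,
    calibration: Calibration,
    threshold_mode: str | float = "otsu",
    min_voxels: int | None = None,
    spline_params: SplineParams | None = None,
    time_min: float = 0.0,
    compute_contours: bool = True,
) -> list[CellObject]:
    """Threshold detection of cell bodies with beta-spline smoothed outlines.

    Touching cells are deliberately kept as one object (aggregates are
    tracked as units); no watershed splitting is attempted.
    """
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("empty intensity grid")
    if min_voxels is None:
        min_voxels = default_min_voxels(calibration)
    if spline_params is None:
        spline_params = SplineParams()
    mask = _foreground(grid, threshold_mode)
    if mask is None:
        return []
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    objects: list[CellObject] = []
    oid = 0
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        count = int(sub.sum())
        if count < min_voxels:
            continue
        vox_local = np.argwhere(sub)
        offset = np.array([s.start for s in sl])
        vox = vox_local + offset
        centroid = vox.mean(axis=0) * np.asarray(calibration.spacing)
        contours = (
            _section_contours(sub, offset, calibration, spline_params)
            if compute_contours
            else {}
        )
        objects.append(
            CellObject(
                object_id=oid,
                time_min=time_min,
                voxels=vox,
                centroid_um=centroid,
                voxel_count=count,
                contours=contours,
            )
        )
        oid += 1
    return objects


def contours_to_json(objects: list[CellObject], path) -> None:
    """Export per-section smoothed contours as JSON.

    Layout: one record per object with id, time and a mapping of z-section
    index to the closed (y, x) μm vertex list.
    """
    import json

    records = [
        {
            "object_id": obj.object_id,
            "time_min": obj.time_min,
            "contours": {str(k): np.round(v, 3).tolist() for k, v in obj.contours.items()},
        }
        for obj in objects
    ]
    with open(path, "w") as fh:
        json.dump(records, fh)


def _section_contours(
    sub: np.ndarray,
    offset: np.ndarray,
    calibration: Calibration,
    params: SplineParams,
) -> dict[int, np.ndarray]:
    """Outer closed contour of each occupied z-section, spline smoothed."""
    contours: dict[int, np.ndarray] = {}
    for kz in range(sub.shape[0]):
        section = sub[kz]
        if not section.any():
            continue
        padded = np.pad(section.astype(float), 1)
        found = measure.find_contours(padded, 0.5)
        if not found:
            continue
        outer = max(found, key=len) - 1.0 + offset[1:]  # back to (row, col) px
        poly = _smooth_closed_contour(outer, params)
        poly_um = poly * np.array([calibration.dy_um, calibration.dx_um])
        contours[kz + int(offset[0])] = poly_um
    return contours


def _smooth_closed_contour(outer: np.ndarray, params: SplineParams) -> np.ndarray:
    """Fit a closed periodic cubic B-spline and resample it.

    Falls back to the raw pixel contour (resampled) for degenerate inputs.
    """
    pts = outer
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 4:
        closed = np.vstack([outer, outer[:1]]) if not np.allclose(outer[0], outer[-1]) else outer
        return closed
    perimeter = float(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1).sum())
    s = 0.5 * perimeter if params.smoothing is None else params.smoothing
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=s, per=1)
        u = np.linspace(0.0, 1.0, params.n_points, endpoint=False)
        ry, rx = interpolate.splev(u, tck)
        poly = np.column_stack([ry, rx])
    except (ValueError, TypeError):
        poly = pts
    return np.vstack([poly, poly[:1]])
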