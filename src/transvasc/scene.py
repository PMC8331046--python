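"""Synthetic 4D two-channel scene generator with ground truth.

The generator emulates the geometry of an endothelial tube-formation assay
imaged by confocal z-stacks: a quasi-planar reticulated multicellular
network sits near a cushion plane at ``z ~ plane_z_um``, and ellipsoidal
cancer cells (default body diameter 30 μm) are dispersed in the overlying
matrix, each executing a programmed motility behavior.  The network can be
eroded over time following a retained-volume schedule, emulating network
disassembly.  Every scene is rendered to intensity volumes (with
configurable noise applied last) together with a voxel-exact ground truth,
so each downstream analysis stage can be validated against known answers.

Determinism: an identical :class:`SceneSpec` (including ``seed``) renders to
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line

from .io import Calibration, ImageSeries4D, DEFAULT_CHANNELS

__all__ = [
    "NoiseSpec",
    "NetworkSpec",
    "CellProgram",
    "SceneSpec",
    "GroundTruth",
    "GenerationError",
    "InvalidScheduleError",
    "build_network",
    "render_scene",
    "make_cohort",
    "make_far_cohort",
    "scene_spec_to_dict",
    "scene_spec_from_dict",
]

PROGRAM_KINDS = (
    "STATIONARY",
    "RANDOM_WALK",
    "DIRECTED_TO_NETWORK",
    "ALONG_NETWORK",
    "PENETRATE_AND_EXIT",
)


#: Directed cells keep moving until their body overlaps the network by this
#: depth (μm) — cells deform onto the substrate at adhesion, and the slight
#: interpenetration makes voxelized contact unambiguous.
CONTACT_OVERSHOOT_UM = 2.0


class GenerationError(RuntimeError):
    """A cell program cannot be realized inside the grid."""


class InvalidScheduleError(ValueError):
    """A decay schedule is not non-increasing within (0, 1]."""


@dataclass(frozen=True)
class NoiseSpec:
    """Intensity model: foreground/background levels on an 8-bit scale,
    Poisson shot noise and additive Gaussian read noise."""

    background: float = 10.0
    foreground: float = 200.0
    gaussian_sd: float = 5.0
    poisson: bool = True


@dataclass(frozen=True)
class NetworkSpec:
    """Planar graph of junctions and branches rendered as tubes.

    Junction positions are ``(y_um, x_um)`` on the cushion plane at
    ``plane_z_um``.  Branches are straight tubes of elliptical cross-section
    (lateral radius ``branch_radius_um``, axial half-thickness
    ``half_thickness_um``).  Junctions may optionally carry a larger
    ellipsoidal node mass (``node_radius_um``), standing in for the
    multicellular node thickening seen in tube-formation assays.
    """

    junctions_um: tuple[tuple[float, float], ...]
    edges: tuple[tuple[int, int], ...]
    plane_z_um: float = 12.5
    branch_radius_um: float = 8.0
    half_thickness_um: float = 7.5
    node_radius_um: float | None = None
    node_half_thickness_um: float | None = None
    decay_seeds: int = 3


@dataclass(frozen=True)
class CellProgram:
    """Motion program of one synthetic cell.

    ``start_um`` is the initial body center ``(z, y, x)`` in μm.  Speeds are
    in μm/min; per-frame step lengths are drawn from
    ``Normal(speed_mean, speed_sd) * dt`` truncated at zero.  For
    ``ALONG_NETWORK`` the cell rides the medial axis of branch
    ``along_edge`` starting at arc-length ``along_start_um``, its center
    held ``along_z_offset_um`` above the network plane.  For
    ``PENETRATE_AND_EXIT`` the cell sits on the surface of junction node
    ``node_index`` and occupies the node interior between
    ``entry_time_min`` (inclusive) and ``exit_time_min`` (exclusive).
    """

    kind: str
    start_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diameter_um: float = 30.0
    speed_mean: float = 0.0
    speed_sd: float = 0.0
    along_edge: int | None = None
    along_start_um: float = 0.0
    along_z_offset_um: float = 12.0
    entry_time_min: float | None = None
    exit_time_min: float | None = None
    node_index: int | None = None
    min_network_distance_um: float | None = None
    filopodium_length_um: float | None = None
    filopodium_radius_um: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in PROGRAM_KINDS:
            raise ValueError(f"unknown program kind {self.kind!r}")
        if self.speed_mean < 0:
            raise ValueError("speed_mean must be >= 0")
        if self.entry_time_min is not None and self.exit_time_min is not None:
            if not self.entry_time_min < self.exit_time_min:
                raise ValueError("entry time must precede exit time")


@dataclass(frozen=True)
class SceneSpec:
    """Complete ground-truth program for one synthetic 4D scene."""

    calibration: Calibration
    shape: tuple[int, int, int]  # (z, y, x) voxels
    n_frames: int
    seed: int
    network: NetworkSpec
    cells: tuple[CellProgram, ...] = ()
    decay_schedule: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    noise: NoiseSpec = NoiseSpec()
    frame_times_min: tuple[float, ...] | None = None

    def times(self) -> np.ndarray:
        if self.frame_times_min is not None:
            t = np.asarray(self.frame_times_min, dtype=float)
            if len(t) != self.n_frames:
                raise ValueError("frame_times_min length must equal n_frames")
            return t
        return np.arange(self.n_frames, dtype=float) * self.calibration.dt_min


@dataclass
class GroundTruth:
    """Voxel-exact per-frame ground truth recorded before noise.

    ``network_masks``: (t, z, y, x) boolean network masks.
    ``cell_labels``: (t, z, y, x) uint16, 0 = background, i+1 = cell i body.
    ``table``: per cell per frame — programmed center, voxel centroid,
    voxel count and true behavioral state.
    ``retained_fraction``: true network voxel fraction per frame relative to
    frame 0.
    """

    network_masks: np.ndarray
    cell_labels: np.ndarray
    table: pd.DataFrame
    retained_fraction: np.ndarray
    centers_um: np.ndarray  # (t, n_cells, 3) programmed centers (z, y, x)


# ---------------------------------------------------------------------------
# network construction


def _check_schedule(schedule: Sequence[tuple[float, float]]) -> np.ndarray:
    sched = np.asarray(sorted(schedule), dtype=float)
    fracs = sched[:, 1]
    if np.any(fracs <= 0) or np.any(fracs > 1):
        raise InvalidScheduleError("retained fractions must lie in (0, 1]")
    if np.any(np.diff(fracs) > 1e-12):
        raise InvalidScheduleError("retained fraction must be non-increasing in time")
    return sched


def _network_geometry(spec: SceneSpec):
    """Rasterize the skeleton lines and return per-plane distance maps."""
    cal = spec.calibration
    net = spec.network
    nz, ny, nx = spec.shape
    lines = np.zeros((ny, nx), dtype=bool)
    junc_px = [
        (int(round(y / cal.dy_um)), int(round(x / cal.dx_um)))
        for y, x in net.junctions_um
    ]
    for i, j in net.edges:
        (y0, x0), (y1, x1) = junc_px[i], junc_px[j]
        rr, cc = draw_line(y0, x0, y1, x1)
        ok = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
        lines[rr[ok], cc[ok]] = True
    if not lines.any():
        raise GenerationError("network has no branches inside the grid")
    d2d = ndimage.distance_transform_edt(~lines, sampling=(cal.dy_um, cal.dx_um))
    return lines, d2d, junc_px


def _frame0_mask(spec: SceneSpec, d2d: np.ndarray) -> np.ndarray:
    cal = spec.calibration
    net = spec.network
    nz, ny, nx = spec.shape
    z_um = np.arange(nz, dtype=float) * cal.dz_um
    dz = (z_um - net.plane_z_um) / net.half_thickness_um
    lateral = d2d / net.branch_radius_um
    mask = lateral[None] ** 2 + dz[:, None, None] ** 2 <= 1.0
    if net.node_radius_um is not None:
        hn = net.node_half_thickness_um or net.half_thickness_um
        yy = np.arange(ny, dtype=float) * cal.dy_um
        xx = np.arange(nx, dtype=float) * cal.dx_um
        for jy, jx in net.junctions_um:
            r2d = np.hypot(yy[:, None] - jy, xx[None, :] - jx) / net.node_radius_um
            blob = r2d[None] ** 2 + ((z_um - net.plane_z_um) / hn)[:, None, None] ** 2 <= 1.0
            mask |= blob
    return mask


def build_network(spec: SceneSpec) -> np.ndarray:
    """Render per-frame network masks following the decay schedule.

    Frame 0 is the full tube network.  Decay removes voxels in order of
    lateral distance from randomly seeded branch points (seeded RNG), which
    consumes branch cross-sections outward from the seeds — retraction-like
    disassembly that can split the network into detached fragments.  The
    per-frame retained voxel count equals ``round(fraction * N0)`` exactly.
    """
    sched = _check_schedule(spec.decay_schedule)
    lines, d2d, _ = _network_geometry(spec)
    mask0 = _frame0_mask(spec, d2d)
    times = spec.times()
    fracs = np.interp(times, sched[:, 0], sched[:, 1])
    masks = np.empty((spec.n_frames, *spec.shape), dtype=bool)
    if np.allclose(fracs, 1.0):
        masks[:] = mask0
        return masks

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, 17])))
    skel_pts = np.argwhere(lines)
    n_seeds = max(1, min(spec.network.decay_seeds, len(skel_pts)))
    seeds = skel_pts[rng.choice(len(skel_pts), size=n_seeds, replace=False)]
    cal = spec.calibration
    # Disassembly retracts along the cords: removal priority is the geodesic
    # distance *through the skeleton* from the seed segments, applied to
    # whole tube cross-sections, so erosion fronts are perpendicular cuts.
    geo = _skeleton_geodesic(lines, seeds, (cal.dy_um, cal.dx_um))
    _, idx = ndimage.distance_transform_edt(
        ~lines, sampling=(cal.dy_um, cal.dx_um), return_indices=True
    )
    prio2d = geo[idx[0], idx[1]]
    vox = np.argwhere(mask0)  # (N, 3) z, y, x
    prio = prio2d[vox[:, 1], vox[:, 2]]
    order = np.argsort(prio, kind="stable")
    n0 = len(vox)
    for t, f in enumerate(fracs):
        k_remove = n0 - int(round(f * n0))
        m = mask0.copy()
        if k_remove > 0:
            gone = vox[order[:k_remove]]
            m[gone[:, 0], gone[:, 1], gone[:, 2]] = False
        masks[t] = m
    return masks


def _skeleton_geodesic(
    lines: np.ndarray, seeds: np.ndarray, sampling: tuple[float, float]
) -> np.ndarray:
    """Geodesic distance (μm) along skeleton pixels from the seed pixels.

    Dijkstra over the 8-connected pixel graph; pixels in disconnected
    skeleton components get a large finite priority (removed last).
    """
    import heapq

    dy, dx = sampling
    pixels = set(map(tuple, np.argwhere(lines)))
    dist = {p: math.inf for p in pixels}
    heap = []
    for p in map(tuple, seeds):
        if p in dist:
            dist[p] = 0.0
            heapq.heappush(heap, (0.0, p))
    offsets = [
        (oy, ox, math.hypot(oy * dy, ox * dx))
        for oy in (-1, 0, 1)
        for ox in (-1, 0, 1)
        if (oy, ox) != (0, 0)
    ]
    while heap:
        d, (y, x) = heapq.heappop(heap)
        if d > dist[(y, x)]:
            continue
        for oy, ox, w in offsets:
            q = (y + oy, x + ox)
            if q in dist and d + w < dist[q]:
                dist[q] = d + w
                heapq.heappush(heap, (d + w, q))
    finite = [v for v in dist.values() if math.isfinite(v)]
    far = (max(finite) if finite else 0.0) + 1.0
    geo = np.full(lines.shape, far + 1.0)
    for (y, x), v in dist.items():
        geo[y, x] = v if math.isfinite(v) else far
    return geo


# ---------------------------------------------------------------------------
# cell motion simulation


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _simulate_positions(
    spec: SceneSpec, masks: np.ndarray
) -> tuple[np.ndarray, list[list[str]]]:
    """Integrate all cell programs; returns centers (t, n, 3) μm and true states."""
    cal = spec.calibration
    dt = cal.dt_min
    n_cells = len(spec.cells)
    times = spec.times()
    centers = np.zeros((spec.n_frames, n_cells, 3), dtype=float)
    states: list[list[str]] = [[""] * n_cells for _ in range(spec.n_frames)]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, 29])))

    # Per-frame EDT (distance to nearest network voxel + its index), computed
    # lazily: only frames visited by DIRECTED_TO_NETWORK or RANDOM_WALK cells
    # with a distance constraint need it.
    edt_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def edt(t: int):
        if t not in edt_cache:
            dist, idx = ndimage.distance_transform_edt(
                ~masks[t], sampling=cal.spacing, return_indices=True
            )
            edt_cache[t] = (dist, idx)
        return edt_cache[t]

    def to_index(p: np.ndarray) -> tuple[int, int, int]:
        ijk = np.round(p / np.asarray(cal.spacing)).astype(int)
        return tuple(np.clip(ijk, 0, np.asarray(spec.shape) - 1))

    def network_distance(t: int, p: np.ndarray) -> tuple[float, np.ndarray]:
        dist, idx = edt(t)
        k = to_index(p)
        target_idx = idx[:, k[0], k[1], k[2]]
        target = target_idx * np.asarray(cal.spacing)
        return float(np.linalg.norm(p - target)), target

    edge_paths = _edge_paths(spec)

    for ci, prog in enumerate(spec.cells):
        r_cell = prog.diameter_um / 2.0
        p = np.asarray(prog.start_um, dtype=float)
        if prog.kind == "ALONG_NETWORK":
            if prog.along_edge is None:
                raise GenerationError(f"cell program {ci}: ALONG_NETWORK needs along_edge")
            path, length = edge_paths[prog.along_edge]
            s = float(prog.along_start_um)
            p = _point_on_path(path, s)
            p = np.array([spec.network.plane_z_um + prog.along_z_offset_um, p[0], p[1]])
        contacted = False
        for t in range(spec.n_frames):
            if prog.kind == "PENETRATE_AND_EXIT":
                inside = (
                    prog.entry_time_min is not None
                    and prog.exit_time_min is not None
                    and prog.entry_time_min <= times[t] < prog.exit_time_min
                )
                if prog.node_index is None:
                    raise GenerationError(f"cell program {ci}: needs node_index")
                ny_, nx_ = spec.network.junctions_um[prog.node_index]
                node_center = np.array([spec.network.plane_z_um, ny_, nx_])
                p = node_center if inside else np.asarray(prog.start_um, dtype=float)
                states[t][ci] = "INSIDE_NETWORK" if inside else "ON_NETWORK"
            elif prog.kind == "STATIONARY":
                states[t][ci] = "FREE"
            elif prog.kind == "RANDOM_WALK":
                states[t][ci] = "FREE"
            elif prog.kind == "ALONG_NETWORK":
                states[t][ci] = "ON_NETWORK"
            elif prog.kind == "DIRECTED_TO_NETWORK":
                states[t][ci] = "ON_NETWORK" if contacted else "APPROACHING"
            centers[t, ci] = p
            if t == spec.n_frames - 1:
                continue
            # advance to next frame
            step = max(0.0, rng.normal(prog.speed_mean, prog.speed_sd)) * dt
            if prog.kind in ("STATIONARY", "PENETRATE_AND_EXIT"):
                pass
            elif prog.kind == "DIRECTED_TO_NETWORK":
                if not contacted:
                    d, target = network_distance(t, p)
                    # travel remaining until the body overlaps the network
                    gap = d - (r_cell - CONTACT_OVERSHOOT_UM)
                    if gap <= 0:
                        contacted = True
                    elif step >= gap:
                        p = p + _unit(target - p) * gap
                        contacted = True
                    else:
                        p = p + _unit(target - p) * step
            elif prog.kind == "RANDOM_WALK":
                direction = _unit(rng.normal(size=3))
                for cand_dir in (direction, -direction):
                    cand = p + cand_dir * step
                    if not _in_bounds(spec, cand, r_cell):
                        continue
                    if prog.min_network_distance_um is not None:
                        d, _ = network_distance(t, cand)
                        if d - r_cell < prog.min_network_distance_um:
                            continue
                    p = cand
                    break
            elif prog.kind == "ALONG_NETWORK":
                path, length = edge_paths[prog.along_edge]
                s = min(max(s + step, r_cell), length - r_cell)
                q = _point_on_path(path, s)
                p = np.array(
                    [spec.network.plane_z_um + prog.along_z_offset_um, q[0], q[1]]
                )
        # final bounds audit over the whole trajectory
        for t in range(spec.n_frames):
            if not _in_bounds(spec, centers[t, ci], r_cell):
                raise GenerationError(
                    f"cell program {ci} ({prog.kind}) leaves the grid at frame {t}"
                )
    return centers, states


def _in_bounds(spec: SceneSpec, p: np.ndarray, r_um: float) -> bool:
    extent = (np.asarray(spec.shape) - 1) * np.asarray(spec.calibration.spacing)
    return bool(np.all(p - r_um >= 0.0) and np.all(p + r_um <= extent))


def _edge_paths(spec: SceneSpec) -> list[tuple[np.ndarray, float]]:
    """Each branch as a 2-point polyline (y, x) μm with its length."""
    paths = []
    for i, j in spec.network.edges:
        a = np.asarray(spec.network.junctions_um[i], dtype=float)
        b = np.asarray(spec.network.junctions_um[j], dtype=float)
        paths.append((np.stack([a, b]), float(np.linalg.norm(b - a))))
    return paths


def _point_on_path(path: np.ndarray, s: float) -> np.ndarray:
    a, b = path
    length = np.linalg.norm(b - a)
    frac = 0.0 if length == 0 else np.clip(s / length, 0.0, 1.0)
    return a + (b - a) * frac


# ---------------------------------------------------------------------------
# rendering


def _ellipsoid_voxels(
    spec: SceneSpec, center: np.ndarray, semi_um: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices whose centers lie inside a physical-space ellipsoid."""
    spacing = np.asarray(spec.calibration.spacing)
    lo = np.maximum(np.floor((center - semi_um) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((center + semi_um) / spacing).astype(int) + 1, np.asarray(spec.shape)
    )
    if np.any(lo >= hi):
        return (np.empty(0, int),) * 3
    zz = np.arange(lo[0], hi[0]) * spacing[0]
    yy = np.arange(lo[1], hi[1]) * spacing[1]
    xx = np.arange(lo[2], hi[2]) * spacing[2]
    inside = (
        ((zz[:, None, None] - center[0]) / semi_um[0]) ** 2
        + ((yy[None, :, None] - center[1]) / semi_um[1]) ** 2
        + ((xx[None, None, :] - center[2]) / semi_um[2]) ** 2
    ) <= 1.0
    kz, ky, kx = np.nonzero(inside)
    return kz + lo[0], ky + lo[1], kx + lo[2]


def render_scene(spec: SceneSpec) -> tuple[ImageSeries4D, GroundTruth]:
    """Render a scene to an intensity series plus ground truth.

    Cells are solid ellipsoids (spheres in physical space; the axial extent
    in voxels is compressed by the z-anisotropy).  Optional filopodia are
    thin cylinders extended toward the nearest network point.  Noise is
    applied last; the ground truth is recorded before noise.
    """
    if len(spec.cells) > np.iinfo(np.uint16).max - 1:
        raise GenerationError("too many cells for uint16 labels")
    masks = build_network(spec)
    centers, states = _simulate_positions(spec, masks)
    cal = spec.calibration
    noise = spec.noise
    times = spec.times()
    n_t, n_cells = spec.n_frames, len(spec.cells)

    labels = np.zeros((n_t, *spec.shape), dtype=np.uint16)
    data = np.empty((n_t, 2, *spec.shape), dtype=np.uint8)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, 43])))
    rows = []
    for t in range(n_t):
        net_img = np.full(spec.shape, noise.background, dtype=float)
        net_img[masks[t]] = noise.foreground
        cell_img = np.full(spec.shape, noise.background, dtype=float)
        for ci, prog in enumerate(spec.cells):
            r = prog.diameter_um / 2.0
            kz, ky, kx = _ellipsoid_voxels(spec, centers[t, ci], np.full(3, r))
            cell_img[kz, ky, kx] = noise.foreground
            labels[t, kz, ky, kx] = ci + 1
            if prog.filopodium_length_um:
                _render_filopodium(spec, cell_img, centers[t, ci], r, prog, masks[t])
            if len(kz) == 0:
                raise GenerationError(f"cell program {ci} renders no voxels at frame {t}")
            centroid = np.array(
                [kz.mean() * cal.dz_um, ky.mean() * cal.dy_um, kx.mean() * cal.dx_um]
            )
            rows.append(
                {
                    "cell_id": ci,
                    "time_min": times[t],
                    "z_um": centroid[0],
                    "y_um": centroid[1],
                    "x_um": centroid[2],
                    "center_z_um": centers[t, ci, 0],
                    "center_y_um": centers[t, ci, 1],
                    "center_x_um": centers[t, ci, 2],
                    "state": states[t][ci],
                    "voxel_count": int(len(kz)),
                }
            )
        for c, img in enumerate((net_img, cell_img)):
            out = img
            if noise.poisson:
                out = rng.poisson(out).astype(float)
            if noise.gaussian_sd > 0:
                out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
            data[t, c] = np.clip(np.round(out), 0, 255).astype(np.uint8)

    n0 = masks[0].sum()
    retained = masks.reshape(n_t, -1).sum(axis=1) / max(n0, 1)
    series = ImageSeries4D(
        data=data, times_min=times, channels=DEFAULT_CHANNELS, calibration=cal
    )
    truth = GroundTruth(
        network_masks=masks,
        cell_labels=labels,
        table=pd.DataFrame(rows),
        retained_fraction=retained,
        centers_um=centers,
    )
    return series, truth


def _render_filopodium(
    spec: SceneSpec,
    img: np.ndarray,
    center: np.ndarray,
    r_cell: float,
    prog: CellProgram,
    mask: np.ndarray,
) -> None:
    """Thin cylinder from the cell surface toward the nearest network voxel."""
    cal = spec.calibration
    if not mask.any():
        return
    dist, idx = ndimage.distance_transform_edt(
        ~mask, sampling=cal.spacing, return_indices=True
    )
    spacing = np.asarray(cal.spacing)
    k = np.clip(
        np.round(center / spacing).astype(int), 0, np.asarray(spec.shape) - 1
    )
    target = idx[:, k[0], k[1], k[2]] * spacing
    direction = _unit(target - center)
    n_steps = max(2, int(prog.filopodium_length_um / min(cal.dx_um, cal.dy_um)))
    for step in np.linspace(0, prog.filopodium_length_um, n_steps):
        p = center + direction * (r_cell + step)
        if not _in_bounds(spec, p, 0.0):
            break
        kz, ky, kx = _ellipsoid_voxels(
            spec, p, np.full(3, max(prog.filopodium_radius_um, cal.dx_um))
        )
        img[kz, ky, kx] = spec.noise.foreground


# ---------------------------------------------------------------------------
# cohort builders


def _strip_network(width_um: float, plane_z_um: float = 20.0) -> NetworkSpec:
    """A horizontal branch spanning the field with a short stub junction."""
    mid = width_um / 2.0
    return NetworkSpec(
        junctions_um=((16.0, 4.0), (16.0, width_um - 4.0), (16.0, mid), (4.0, mid)),
        edges=((0, 2), (2, 1), (2, 3)),
        plane_z_um=plane_z_um,
    )


def _derive_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def make_cohort(
    calibration: Calibration,
    n_cells: int,
    fraction_reaching: float,
    distance_band: tuple[float, float],
    seed: int,
    n_frames: int = 18,
    cells_per_scene: int = 10,
    noise: NoiseSpec = NoiseSpec(),
    lane_spacing_um: float = 36.0,
) -> list[SceneSpec]:
    """Build scenes for a distance-binned contact/adhesion cohort.

    Exactly ``round(fraction_reaching * n_cells)`` cells are programmed as
    ``DIRECTED_TO_NETWORK`` reachers whose (deterministic) speed brings them
    into contact several frames before the movie ends; the remainder are
    ``STATIONARY`` and never approach the contact threshold.  Initial
    cell-surface-to-network-surface distances are drawn inside
    ``distance_band``.  The cohort is sharded over several scenes (one lane
    per cell) so cells never collide or merge; per-scene seeds derive from
    ``seed``.
    """
    if not 0.0 <= fraction_reaching <= 1.0:
        raise ValueError("fraction_reaching must lie in [0, 1]")
    lo, hi = distance_band
    lo = max(lo, 6.0)  # keep non-contact at t=0
    hi = hi - 2.0  # voxel-rounding margin so measured distances stay in band
    if hi <= lo:
        raise GenerationError(f"distance band {distance_band} is infeasible")
    n_reach = int(round(fraction_reaching * n_cells))
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 7])))
    dt = calibration.dt_min
    arrive_margin = 5  # frames of guaranteed contact before the movie ends
    scenes = []
    placed = reachers_placed = 0
    scene_idx = 0
    while placed < n_cells:
        k = min(cells_per_scene, n_cells - placed)
        n_reach_here = min(k, max(0, n_reach - reachers_placed))
        width = 2 * 24.0 + lane_spacing_um * (k - 1) if k > 1 else 64.0
        net = _strip_network(width)
        r_branch = net.branch_radius_um
        cells = []
        for lane in range(k):
            d = float(rng.uniform(lo, hi))
            x = 24.0 + lane * lane_spacing_um
            y = 16.0 + r_branch + 15.0 + d
            # cell center sits at the tube's mid-plane height so approach is
            # purely lateral and programmed distances match measured ones
            start = (20.0, y, x)
            if lane < n_reach_here:
                n_steps = n_frames - 1 - arrive_margin
                # distance to overlapping contact, with voxel-rounding slack
                travel = d + CONTACT_OVERSHOOT_UM + 1.0
                speed = travel / (n_steps * dt) * 1.05  # arrive before margin
                cells.append(
                    CellProgram("DIRECTED_TO_NETWORK", start_um=start, speed_mean=speed)
                )
            else:
                cells.append(CellProgram("STATIONARY", start_um=start))
        shape = (20, int(math.ceil((16.0 + r_branch + 15.0 + hi + 15.0 + 8.0))), int(width))
        scenes.append(
            SceneSpec(
                calibration=calibration,
                shape=shape,
                n_frames=n_frames,
                seed=_derive_seed(seed, 100 + scene_idx),
                network=net,
                cells=tuple(cells),
                noise=noise,
            )
        )
        placed += k
        reachers_placed += n_reach_here
        scene_idx += 1
    return scenes


def make_far_cohort(
    calibration: Calibration,
    n_cells: int,
    fraction_nontranslocating: float,
    min_distance_um: float,
    seed: int,
    n_frames: int = 18,
    cells_per_scene: int = 10,
    noise: NoiseSpec = NoiseSpec(),
    mover_speed: float = 0.40,
    lane_spacing_um: float = 36.0,
) -> list[SceneSpec]:
    """Far-band cohort: a programmed fraction of non-translocating cells.

    Non-translocators are STATIONARY or small-step RANDOM_WALK cells whose
    net displacement stays well under one cell diameter; the remainder are
    directed movers that translocate toward the network without reaching
    contact within the movie.
    """
    n_still = int(round(fraction_nontranslocating * n_cells))
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 11])))
    dt = calibration.dt_min
    travel = mover_speed * dt * (n_frames - 1)
    scenes = []
    placed = still_placed = 0
    scene_idx = 0
    while placed < n_cells:
        k = min(cells_per_scene, n_cells - placed)
        n_still_here = min(k, max(0, n_still - still_placed))
        width = 2 * 24.0 + lane_spacing_um * (k - 1) if k > 1 else 64.0
        net = _strip_network(width)
        r_branch = net.branch_radius_um
        cells = []
        for lane in range(k):
            d = float(rng.uniform(min_distance_um + 2.0, min_distance_um + 25.0))
            x = 24.0 + lane * lane_spacing_um
            y = 16.0 + r_branch + 15.0 + d
            start = (20.0, y, x)
            if lane < n_still_here:
                if lane % 2 == 0:
                    cells.append(CellProgram("STATIONARY", start_um=start))
                else:
                    cells.append(
                        CellProgram(
                            "RANDOM_WALK",
                            start_um=start,
                            speed_mean=0.08,
                            speed_sd=0.03,
                            min_network_distance_um=min_distance_um - 15.0,
                        )
                    )
            else:
                # mover: translocates toward the network but the band keeps
                # it from reaching contact within the movie
                cells.append(
                    CellProgram("DIRECTED_TO_NETWORK", start_um=start, speed_mean=mover_speed)
                )
        hi = min_distance_um + 25.0
        if travel >= min_distance_um - 10.0:
            raise GenerationError(
                "movers would reach contact inside the far band; "
                "reduce n_frames or mover_speed"
            )
        shape = (20, int(math.ceil(16.0 + r_branch + 15.0 + hi + 15.0 + 8.0)), int(width))
        scenes.append(
            SceneSpec(
                calibration=calibration,
                shape=shape,
                n_frames=n_frames,
                seed=_derive_seed(seed, 200 + scene_idx),
                network=net,
                cells=tuple(cells),
                noise=noise,
            )
        )
        placed += k
        still_placed += n_still_here
        scene_idx += 1
    return scenes


# ---------------------------------------------------------------------------
# (de)serialization for YAML configs


def scene_spec_to_dict(spec: SceneSpec) -> dict:
    d = asdict(spec)
    d["calibration"] = asdict(spec.calibration)
    return d


def scene_spec_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    cal = Calibration(**d.pop("calibration"))
    net_d = dict(d.pop("network"))
    net_d["junctions_um"] = tuple(tuple(p) for p in net_d["junctions_um"])
    net_d["edges"] = tuple(tuple(e) for e in net_d["edges"])
    net = NetworkSpec(**net_d)
    cells = tuple(
        CellProgram(**{**c, "start_um": tuple(c["start_um"])}) for c in d.pop("cells", ())
    )
    noise = NoiseSpec(**d.pop("noise")) if "noise" in d else NoiseSpec()
    sched = tuple(tuple(s) for s in d.pop("decay_schedule", ((0.0, 1.0),)))
    ft = d.pop("frame_times_min", None)
    return SceneSpec(
        calibration=cal,
        shape=tuple(d.pop("shape")),
        n_frames=int(d.pop("n_frames")),
        seed=int(d.pop("seed")),
        network=net,
        cells=cells,
        decay_schedule=sched,
        noise=noise,
        frame_times_min=tuple(ft) if ft is not None else None,
    )
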