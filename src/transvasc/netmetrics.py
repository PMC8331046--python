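"""Network topology and decay metrics: skeleton, nodes, percent decrease.

The reticulated endothelial network is quasi-planar, so topology is read
from a 2D skeleton of the maximum-intensity z-projection (3D thinning on
coarse anisotropic z-steps is unstable), while surface areas remain fully
3D (faceted marching-cubes reconstructions).  A node is a skeleton junction
where at least three branches meet; connected mask components carrying no
node are "detached" fragments and can be excluded from the analyzed area.
Percent decrease of network surface area is reported relative to a
reference frame (conventionally the 4-hour network).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .io import Calibration
from .segmentation import BinaryVolume
from .surfaces import surface_from_mask

__all__ = [
    "SkeletonGraph",
    "NetworkModel",
    "DecayReport",
    "skeletonize_network",
    "assign_node_regions",
    "build_network_model",
    "decay_report",
]

_OFFSETS = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


@dataclass
class SkeletonGraph:
    """2D skeleton of the projected network as a junction/branch graph.

    ``graph`` is a :class:`networkx.MultiGraph` whose nodes are
    ``("J", id)`` junction clusters or ``("E", id)`` free branch ends, each
    with a ``pos`` attribute (pixel ``(row, col)``); edges carry
    ``length_um`` and the branch pixel polyline.  ``junction_pixels`` maps
    junction id to its member skeleton pixels (clusters adjacent within one
    pixel are merged, as are clusters joined by branches shorter than the
    pruning length).
    """

    skeleton: np.ndarray
    graph: nx.MultiGraph
    junction_pixels: dict[int, np.ndarray] = field(default_factory=dict)
    calibration: Calibration | None = None

    @property
    def node_ids(self) -> list[int]:
        """Junctions of degree >= 3 (the network's nodes)."""
        return sorted(
            j for (kind, j) in self.graph.nodes if kind == "J" and self.graph.degree(("J", j)) >= 3
        )

    @property
    def n_branches(self) -> int:
        return self.graph.number_of_edges()

    def junction_positions_um(self) -> dict[int, np.ndarray]:
        cal = self.calibration or Calibration()
        return {
            j: np.asarray(self.graph.nodes[("J", j)]["pos"]) * np.array([cal.dy_um, cal.dx_um])
            for j in self.node_ids
        }


def _neighbors(p: tuple[int, int], pixels: set[tuple[int, int]]):
    y, x = p
    for dy, dx in _OFFSETS:
        q = (y + dy, x + dx)
        if q in pixels:
            yield q


def _trace_branches(pixels: set, junction_label: dict):
    """Split skeleton pixels into branch polylines.

    Each branch is returned as ``(path, j0, j1)`` where ``path`` is the
    ordered pixel list and ``j0``/``j1`` are the junction pixels adjacent to
    its ends (``None`` for a free end).
    """
    branch_pixels = {p for p in pixels if p not in junction_label}
    visited: set = set()
    branches = []

    def junction_nbrs(p):
        return [q for q in _neighbors(p, pixels) if q in junction_label]

    starts = []
    for p in sorted(branch_pixels):
        n_branch_nbrs = sum(1 for q in _neighbors(p, pixels) if q in branch_pixels)
        if n_branch_nbrs <= 1 or junction_nbrs(p):
            starts.append(p)
    for start in starts:
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = [
                q for q in _neighbors(cur, pixels) if q in branch_pixels and q not in visited
            ]
            if not nxt:
                break
            cur = nxt[0]
            path.append(cur)
            visited.add(cur)
        head = junction_nbrs(path[0])
        tail = junction_nbrs(path[-1])
        j0 = head[0] if head else None
        if len(path) == 1:
            j1 = None
            for q in tail:
                if j0 is not None and junction_label[q] != junction_label[j0]:
                    j1 = q
                    break
        else:
            j1 = tail[0] if tail else None
        branches.append((path, j0, j1))
    # isolated cycles (ring with no junction and no free end)
    for p in sorted(branch_pixels - visited):
        path = [p]
        visited.add(p)
        cur = p
        while True:
            nxt = [q for q in _neighbors(cur, pixels) if q in branch_pixels and q not in visited]
            if not nxt:
                break
            cur = nxt[0]
            path.append(cur)
            visited.add(cur)
        branches.append((path, None, None))
    return branches


def skeletonize_network(
    mask: BinaryVolume | np.ndarray,
    calibration: Calibration | None = None,
    prune_um: float = 5.0,
) -> SkeletonGraph:
    """Skeletonize the z-projection of a network mask into a branch graph.

    Spur branches shorter than ``prune_um`` are pruned before the node
    census (skeletonization artifacts would otherwise inflate junction
    counts; a real multicellular branch is far longer), and junction
    clusters joined by branches shorter than ``prune_um`` are merged.
    """
    if isinstance(mask, BinaryVolume):
        calibration = mask.calibration
        arr = mask.mask
    else:
        if calibration is None:
            calibration = Calibration()
        arr = np.asarray(mask, dtype=bool)
    proj = arr.max(axis=0) if arr.ndim == 3 else arr
    if not proj.any():
        return SkeletonGraph(np.zeros_like(proj), nx.MultiGraph(), {}, calibration)
    skel = skeletonize(proj)
    graph, junction_pixels = _analyze_skeleton(skel, calibration)
    graph, junction_pixels = _prune_graph(graph, junction_pixels, prune_um)
    return SkeletonGraph(skel, graph, junction_pixels, calibration)


def _analyze_skeleton(skel: np.ndarray, cal: Calibration):
    pixels = set(map(tuple, np.argwhere(skel)))
    degree = {p: sum(1 for _ in _neighbors(p, pixels)) for p in pixels}
    junction_px = [p for p, d in degree.items() if d >= 3]
    # merge junction pixels adjacent within one pixel into clusters
    junction_label: dict[tuple[int, int], int] = {}
    clusters: dict[int, list] = {}
    jset = set(junction_px)
    cid = 0
    for p in sorted(jset):
        if p in junction_label:
            continue
        queue = deque([p])
        junction_label[p] = cid
        members = [p]
        while queue:
            cur = queue.popleft()
            for q in _neighbors(cur, jset):
                if q not in junction_label:
                    junction_label[q] = cid
                    members.append(q)
                    queue.append(q)
        clusters[cid] = members
        cid += 1

    graph = nx.MultiGraph()
    for j, members in clusters.items():
        pos = tuple(np.mean(members, axis=0))
        graph.add_node(("J", j), pos=pos)
    step = np.array([cal.dy_um, cal.dx_um])
    eid = 0
    for path, j0, j1 in _trace_branches(pixels, junction_label):
        pts = np.asarray(path, dtype=float)
        seg = 0.0
        if len(pts) > 1:
            seg = float(np.linalg.norm(np.diff(pts, axis=0) * step, axis=1).sum())
        ends = []
        for j, endpoint in ((j0, path[0]), (j1, path[-1])):
            if j is not None:
                ends.append(("J", junction_label[j]))
                seg += float(np.linalg.norm((np.asarray(endpoint) - np.asarray(j)) * step))
            else:
                ends.append(("E", eid))
                graph.add_node(("E", eid), pos=tuple(map(float, endpoint)))
                eid += 1
        if path and len(path) >= 1:
            graph.add_edge(ends[0], ends[1], length_um=seg, pixels=np.asarray(path))
    junction_pixels = {j: np.asarray(m) for j, m in clusters.items()}
    return graph, junction_pixels


def _prune_graph(graph: nx.MultiGraph, junction_pixels: dict, prune_um: float):
    graph = graph.copy()
    # 1. drop spur branches (one free end) shorter than the pruning length
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(graph.edges(keys=True, data=True)):
            if d["length_um"] >= prune_um:
                continue
            if u[0] == "E" or v[0] == "E":
                graph.remove_edge(u, v, key=k)
                for n in (u, v):
                    if n in graph and n[0] == "E" and graph.degree(n) == 0:
                        graph.remove_node(n)
                changed = True
    # 2. contract junction-junction branches shorter than the pruning length
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(graph.edges(keys=True, data=True)):
            if u == v or d["length_um"] >= prune_um:
                continue
            if u[0] == "J" and v[0] == "J":
                graph = nx.contracted_nodes(graph, u, v, self_loops=False)
                junction_pixels[u[1]] = np.vstack(
                    [junction_pixels[u[1]], junction_pixels.pop(v[1])]
                )
                changed = True
                break
    # drop isolated junction nodes left behind
    for n in [n for n in graph.nodes if graph.degree(n) == 0 and n[0] == "E"]:
        graph.remove_node(n)
    return graph, junction_pixels


@dataclass
class NetworkModel:
    """One frame of the network: mask, skeleton graph, regions and areas."""

    time_min: float
    mask: BinaryVolume
    skeleton: SkeletonGraph
    analyzed_mask: np.ndarray
    region_labels: np.ndarray | None = None
    node_areas_um2: dict[int, float] = field(default_factory=dict)
    total_area_um2: float = 0.0
    detached_voxels: int = 0


def assign_node_regions(
    mask: BinaryVolume,
    skeleton: SkeletonGraph,
    exclude_detached: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Partition mask voxels among nodes; flag detached fragments.

    Every analyzed voxel is assigned to the node (degree-≥3 junction)
    nearest through the skeleton: skeleton pixels take the label of the
    geodesically nearest junction cluster, and each mask voxel inherits the
    label of its nearest skeleton pixel.  Connected components whose
    projection contains no node are DETACHED and excluded when the flag is
    set.  Returns ``(region_labels, analyzed_mask, detached_voxel_count)``
    where ``region_labels`` is 0 outside, node_id + 1 inside.
    """
    arr = mask.mask
    node_ids = skeleton.node_ids
    if not node_ids:
        warnings.warn("network has no nodes; falling back to whole-mask analysis", stacklevel=2)
        return (arr.astype(np.int32), arr.copy(), 0)

    pixels = set(map(tuple, np.argwhere(skeleton.skeleton)))
    label_of: dict[tuple[int, int], int] = {}
    queue: deque = deque()
    for j in node_ids:
        for p in map(tuple, skeleton.junction_pixels[j]):
            if p in pixels:
                label_of[p] = j
                queue.append(p)
    while queue:
        cur = queue.popleft()
        for q in _neighbors(cur, pixels):
            if q not in label_of:
                label_of[q] = label_of[cur]
                queue.append(q)
    labeled_px = np.array(sorted(label_of), dtype=int)
    labels_1d = np.array([label_of[tuple(p)] for p in labeled_px], dtype=np.int32)

    # nearest labeled skeleton pixel for every (y, x) column
    seed = np.ones(arr.shape[1:], dtype=bool)
    seed[labeled_px[:, 0], labeled_px[:, 1]] = False
    cal = mask.calibration
    _, idx = ndimage.distance_transform_edt(
        seed, sampling=(cal.dy_um, cal.dx_um), return_indices=True
    )
    label_2d = np.zeros(arr.shape[1:], dtype=np.int32)
    label_2d[labeled_px[:, 0], labeled_px[:, 1]] = labels_1d + 1
    nearest_label = label_2d[idx[0], idx[1]]

    region = np.where(arr, nearest_label[None, :, :], 0).astype(np.int32)

    # detached components: no node pixel in their projection
    comp, n_comp = ndimage.label(arr, structure=np.ones((3, 3, 3), bool))
    node_px_mask = np.zeros(arr.shape[1:], dtype=bool)
    for j in node_ids:
        px = skeleton.junction_pixels[j]
        node_px_mask[px[:, 0], px[:, 1]] = True
    detached = 0
    analyzed = arr.copy()
    for c in range(1, n_comp + 1):
        proj = (comp == c).any(axis=0)
        if not (proj & node_px_mask).any():
            voxels = comp == c
            detached += int(voxels.sum())
            if exclude_detached:
                analyzed[voxels] = False
                region[voxels] = 0
    return region, analyzed, detached


def build_network_model(
    mask: BinaryVolume,
    exclude_detached: bool = True,
    prune_um: float = 5.0,
    smooth_sigma: float = 0.5,
    compute_node_areas: bool = False,
) -> NetworkModel:
    """Skeletonize, partition into node regions and measure faceted areas."""
    skeleton = skeletonize_network(mask, prune_um=prune_um)
    region, analyzed, detached = assign_node_regions(mask, skeleton, exclude_detached)
    surf = surface_from_mask(
        analyzed, mask.calibration, smooth_sigma=smooth_sigma,
        provenance=f"network t={mask.time_min}",
    )
    model = NetworkModel(
        time_min=mask.time_min,
        mask=mask,
        skeleton=skeleton,
        analyzed_mask=analyzed,
        region_labels=region,
        total_area_um2=surf.total_area_um2,
        detached_voxels=detached,
    )
    if compute_node_areas:
        for j in skeleton.node_ids:
            sub = region == j + 1
            if sub.any():
                s = surface_from_mask(sub, mask.calibration, smooth_sigma=smooth_sigma)
                model.node_areas_um2[j] = s.total_area_um2
    return model


@dataclass
class DecayReport:
    """Percent decrease of analyzed network surface area vs the reference.

    ``frames`` has one row per frame (``time_min``, ``area_um2``,
    ``percent_decrease`` on a 0–100 scale, 0 at the reference frame);
    ``per_node`` has one row per persisting node per frame.  Node identity
    across frames is matched by nearest reference junction within
    ``match_radius_um``.
    """

    frames: "object"  # pandas.DataFrame
    per_node: "object"
    reference_time_min: float
    match_radius_um: float = 15.0


def decay_report(
    models: list[NetworkModel],
    reference_time_min: float,
    match_radius_um: float = 15.0,
) -> DecayReport:
    import pandas as pd

    times = [m.time_min for m in models]
    if reference_time_min not in times:
        raise ValueError(f"reference frame t={reference_time_min} not in series {times}")
    ref = models[times.index(reference_time_min)]
    if ref.total_area_um2 <= 0:
        raise ZeroDivisionError("reference network area is zero; report undefined")
    rows = [
        {
            "time_min": m.time_min,
            "area_um2": m.total_area_um2,
            "percent_decrease": 100.0 * (1.0 - m.total_area_um2 / ref.total_area_um2),
        }
        for m in models
    ]
    node_rows = []
    ref_pos = ref.skeleton.junction_positions_um()
    for m in models:
        pos = m.skeleton.junction_positions_um()
        for rj, rp in ref_pos.items():
            ref_area = ref.node_areas_um2.get(rj)
            if not ref_area:
                continue
            best, best_d = None, match_radius_um
            for j, p in pos.items():
                d = float(np.linalg.norm(p - rp))
                if d <= best_d:
                    best, best_d = j, d
            if best is None:
                continue
            area = m.node_areas_um2.get(best)
            if area is None:
                continue
            node_rows.append(
                {
                    "time_min": m.time_min,
                    "ref_node": rj,
                    "node": best,
                    "area_um2": area,
                    "percent_decrease": 100.0 * (1.0 - area / ref_area),
                }
            )
    return DecayReport(
        frames=pd.DataFrame(rows),
        per_node=pd.DataFrame(node_rows),
        reference_time_min=reference_time_min,
        match_radius_um=match_radius_um,
    )
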