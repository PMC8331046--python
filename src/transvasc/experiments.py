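"""Parameter-recovery experiments on synthetic scenes.

Each experiment programs the synthetic generator with a published behavior
statistic (a cohort speed distribution, a decay schedule, a reach
fraction), runs the *full* analysis pipeline — render, segment,
reconstruct, track, classify — and reports the recovered quantity.  The
study conditions (cohort sizes, speed distributions, decay schedules,
distance bands) mirror the live-imaging cohorts being emulated; grids and
frame counts are desk-scale so a whole suite runs on one CPU in minutes,
with cohorts sharded over several fields of view exactly as a microscope
samples several regions per dish.
"""

from __future__ import annotations

import numpy as np

from .behavior import population_summary
from .io import Calibration
from .pipeline import RunConfig, analyze_series
from .scene import (
    CellProgram,
    NetworkSpec,
    NoiseSpec,
    SceneSpec,
    make_cohort,
    make_far_cohort,
    render_scene,
)
from .tracking import compare_cohorts, velocity_stats

__all__ = [
    "approach_velocity_recovery",
    "along_velocity_recovery",
    "decay_recovery",
    "near_band_adhesion",
    "far_band_nontranslocation",
    "detachment_rate",
    "penetration_timing",
    "perturbation_velocity_drop",
    "DECAY_SCHEDULES",
    "lattice_network",
    "matrigel_cohort_scenes",
    "along_scenes",
    "pooled_tracks",
    "penetration_scene",
    "SUITES",
]

#: Default calibration of every experiment: 1-μm lateral pixels, 2.5-μm
#: z-steps, 10-min frames (the z-count per scene is set by the grid shape).
CAL = Calibration(dx_um=1.0, dy_um=1.0, dz_um=2.5, dt_min=10.0, n_z=60)

NOISE_FREE = NoiseSpec(gaussian_sd=0.0, poisson=False)

#: Published percent decreases of network surface area at 24 h / 48 h for
#: the three overlay conditions, expressed as retained-fraction schedules
#: (time in minutes; the 4-h network is the reference).
DECAY_SCHEDULES: dict[str, tuple[tuple[float, float], ...]] = {
    "no_cells": ((240.0, 1.0), (1440.0, 0.83), (2880.0, 0.72)),
    "mcf10a": ((240.0, 1.0), (1440.0, 0.25), (2880.0, 0.10)),
    "mb231": ((240.0, 1.0), (1440.0, 0.69), (2880.0, 0.58)),
}


def _seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# velocity cohorts


def matrigel_cohort_scenes(
    seed: int,
    n_cells: int,
    speed_mean: float,
    speed_sd: float,
    n_frames: int = 13,
    cells_per_scene: int = 10,
    noise: NoiseSpec = NoiseSpec(),
) -> list[SceneSpec]:
    """Cells translocating through the matrix toward a distant network.

    Each cell is placed far enough that it cannot reach contact within the
    movie, so every step reflects free directed translocation at the
    programmed speed distribution.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 3])))
    lane = 36.0
    scenes = []
    placed = 0
    idx = 0
    # worst-case travel keeps cells clear of contact
    margin = (speed_mean + 4.0 * speed_sd) * CAL.dt_min * (n_frames - 1) + 10.0
    while placed < n_cells:
        k = min(cells_per_scene, n_cells - placed)
        width = 2 * 24.0 + lane * (k - 1) if k > 1 else 64.0
        mid = width / 2.0
        net = NetworkSpec(
            junctions_um=((16.0, 4.0), (16.0, width - 4.0), (16.0, mid), (4.0, mid)),
            edges=((0, 2), (2, 1), (2, 3)),
            plane_z_um=20.0,
        )
        cells = []
        for j in range(k):
            d = float(rng.uniform(margin, margin + 20.0))
            cells.append(
                CellProgram(
                    "DIRECTED_TO_NETWORK",
                    start_um=(20.0, 16.0 + 8.0 + 15.0 + d, 24.0 + j * lane),
                    speed_mean=speed_mean,
                    speed_sd=speed_sd,
                )
            )
        ny = int(np.ceil(16.0 + 8.0 + 15.0 + margin + 20.0 + 15.0 + 8.0))
        scenes.append(
            SceneSpec(
                calibration=CAL,
                shape=(20, ny, int(width)),
                n_frames=n_frames,
                seed=_seed(seed, 300 + idx),
                network=net,
                cells=tuple(cells),
                noise=noise,
            )
        )
        placed += k
        idx += 1
    return scenes


def pooled_tracks(scenes: list[SceneSpec], config: RunConfig | None = None):
    if config is None:
        # centroid tracking does not need spline outlines
        config = RunConfig(input_path="-", calibration=CAL)
        config.segmentation.compute_contours = False
    tracks, annotated = [], []
    for spec in scenes:
        series, _ = render_scene(spec)
        res = analyze_series(series, config)
        tracks.extend(res.tracks)
        annotated.extend(res.annotated)
    return tracks, annotated


def approach_velocity_recovery(
    seed: int,
    n_cells: int = 50,
    speed_mean: float = 0.40,
    speed_sd: float = 0.08,
) -> dict:
    """Recover the mean approach speed of a directed-translocation cohort.

    The cohort is programmed from the published approach statistics
    (0.40 ± 0.08 μm/min, N = 50) and measured as the cohort mean of
    per-track mean 3D centroid speeds after segmentation and tracking.
    """
    scenes = matrigel_cohort_scenes(seed, n_cells, speed_mean, speed_sd)
    tracks, _ = pooled_tracks(scenes)
    speeds = [tr.mean_speed_um_min for tr in tracks if len(tr) >= 6]
    return {"value": float(np.mean(speeds)), "n": len(speeds), "sd": float(np.std(speeds, ddof=1))}


def along_scenes(
    seed: int,
    n_cells: int,
    speed_mean: float,
    speed_sd: float,
    n_frames: int = 13,
    cells_per_scene: int = 4,
    noise: NoiseSpec = NoiseSpec(),
) -> list[SceneSpec]:
    """Cells riding the medial axis of long straight branches (one per comb
    tooth, so aggregates never form)."""
    scenes = []
    placed = 0
    idx = 0
    tooth_y0, tooth_dy = 36.0, 48.0
    x0, x1 = 16.0, 240.0
    while placed < n_cells:
        k = min(cells_per_scene, n_cells - placed)
        junctions = [(tooth_y0 + i * tooth_dy, x0) for i in range(k)]
        spine = [(junctions[0][0], x0), (junctions[-1][0], x0)]
        pts = junctions + [(y, x1) for y, _ in junctions]
        edges = []
        # teeth
        for i in range(k):
            edges.append((i, k + i))
        # spine segments
        for i in range(k - 1):
            edges.append((i, i + 1))
        net = NetworkSpec(junctions_um=tuple(pts), edges=tuple(edges))
        cells = tuple(
            CellProgram(
                "ALONG_NETWORK",
                speed_mean=speed_mean,
                speed_sd=speed_sd,
                along_edge=i,
                along_start_um=40.0,
                along_z_offset_um=12.0,
            )
            for i in range(k)
        )
        ny = int(tooth_y0 + (k - 1) * tooth_dy + 36.0)
        scenes.append(
            SceneSpec(
                calibration=CAL,
                shape=(20, ny, 256),
                n_frames=n_frames,
                seed=_seed(seed, 400 + idx),
                network=net,
                cells=cells,
                noise=noise,
            )
        )
        placed += k
        idx += 1
    return scenes


def along_velocity_recovery(
    seed: int,
    n_cells: int = 20,
    speed_mean: float = 0.73,
    speed_sd: float = 0.31,
) -> dict:
    """Recover the mean on-network translocation speed (0.73 ± 0.31, N = 20).

    Speeds are averaged over ON_NETWORK-labeled frames only, per track,
    then over the cohort.
    """
    scenes = along_scenes(seed, n_cells, speed_mean, speed_sd)
    _, annotated = pooled_tracks(scenes)
    per_track = []
    for ann in annotated:
        if len(ann.track) < 6:
            continue
        _, speeds, _ = velocity_stats(ann.track)
        on = [speeds[i] for i, s in enumerate(ann.states[:-1]) if s == "ON_NETWORK"]
        if on:
            per_track.append(float(np.mean(on)))
    return {
        "value": float(np.mean(per_track)),
        "n": len(per_track),
        "sd": float(np.std(per_track, ddof=1)),
    }


# ---------------------------------------------------------------------------
# network decay


def lattice_network(n: int = 4, spacing: float = 80.0, start: float = 40.0) -> NetworkSpec:
    """A reticulated n×n lattice of 80-μm cords (realistic mesh size)."""
    pts = [(start + spacing * r, start + spacing * c) for r in range(n) for c in range(n)]
    edges = []
    for r in range(n):
        for c in range(n):
            i = n * r + c
            if c < n - 1:
                edges.append((i, i + 1))
            if r < n - 1:
                edges.append((i, i + n))
    return NetworkSpec(junctions_um=tuple(pts), edges=tuple(edges), decay_seeds=2)


def decay_recovery(seed: int, condition: str, noise: NoiseSpec = NoiseSpec()) -> dict:
    """Percent decrease of faceted network area at 48 h for one condition.

    A reticulated lattice network is eroded to the retained-volume schedule
    of the condition, rendered, re-segmented, reconstructed and measured by
    the decay pipeline with the 4-h frame as reference.
    """
    schedule = DECAY_SCHEDULES[condition]
    spec = SceneSpec(
        calibration=CAL,
        shape=(12, 400, 400),
        n_frames=3,
        seed=_seed(seed, 500 + sum(map(ord, condition))),
        network=lattice_network(),
        cells=(),
        decay_schedule=schedule,
        noise=noise,
        frame_times_min=tuple(t for t, _ in schedule),
    )
    from .netmetrics import build_network_model, decay_report
    from .segmentation import segment_network

    series, _ = render_scene(spec)
    models = []
    for t in range(series.n_frames):
        mask = segment_network(
            series.frame(t, "network"), CAL, time_min=float(series.times_min[t])
        )
        # retention measurement keeps every fragment: detachment is part of
        # the programmed disassembly being quantified
        models.append(build_network_model(mask, exclude_detached=False))
    report = decay_report(models, reference_time_min=240.0)
    row = report.frames.loc[report.frames["time_min"] == 2880.0].iloc[0]
    return {"value": float(row["percent_decrease"]), "n": int(series.n_frames)}


# ---------------------------------------------------------------------------
# contact / adhesion cohorts


def near_band_adhesion(
    seed: int,
    n_cells: int = 100,
    fraction_reaching: float = 0.68,
    noise: NoiseSpec = NOISE_FREE,
) -> dict:
    """Adhered fraction of a near-band (≤65 μm) cohort, percent.

    68 of 100 cells are programmed to translocate to and adhere to the
    network; the pipeline must count exactly the adhering tracks.
    """
    scenes = make_cohort(
        CAL, n_cells, fraction_reaching, (0.0, 65.0), seed=_seed(seed, 600), noise=noise
    )
    _, annotated = pooled_tracks(scenes)
    summary = population_summary(annotated)
    near = summary.loc[summary["bin"] == "near"].iloc[0]
    return {"value": 100.0 * float(near["adhered_fraction"]), "n": int(near["n"])}


def far_band_nontranslocation(
    seed: int,
    n_cells: int = 100,
    fraction_nontranslocating: float = 0.35,
    noise: NoiseSpec = NOISE_FREE,
) -> dict:
    """Non-translocating fraction of a far-band (≥80 μm) cohort, percent.

    35 of 100 cells are programmed as stationary or randomly wandering
    (net displacement under one cell diameter); the rest translocate
    directionally without reaching contact.
    """
    scenes = make_far_cohort(
        CAL, n_cells, fraction_nontranslocating, 80.0, seed=_seed(seed, 700), noise=noise
    )
    _, annotated = pooled_tracks(scenes)
    summary = population_summary(annotated)
    far = summary.loc[summary["bin"] == "far"].iloc[0]
    return {"value": 100.0 * float(far["nontranslocating_fraction"]), "n": int(far["n"])}


def detachment_rate(seed: int, n_cells: int = 100, noise: NoiseSpec = NOISE_FREE) -> dict:
    """Detachment fraction among adhered cells programmed never to release.

    Every cell reaches adhesion and stays in contact through the final
    frame; the pipeline must report zero DETACH events.
    """
    scenes = make_cohort(
        CAL, n_cells, 1.0, (0.0, 50.0), seed=_seed(seed, 800), n_frames=14, noise=noise
    )
    _, annotated = pooled_tracks(scenes)
    summary = population_summary(annotated)
    near = summary.loc[summary["bin"] == "near"].iloc[0]
    adhered = int(round(near["adhered_fraction"] * near["n"]))
    return {"value": 100.0 * float(near["detach_fraction"]), "n": adhered}


# ---------------------------------------------------------------------------
# penetration


def penetration_scene(seed: int, noise: NoiseSpec = NOISE_FREE) -> tuple[SceneSpec, list]:
    """Three cells penetrating node masses at programmed entry/exit times."""
    junctions = ((64.0, 40.0), (64.0, 128.0), (64.0, 216.0))
    net = NetworkSpec(
        junctions_um=junctions,
        edges=((0, 1), (1, 2)),
        plane_z_um=25.0,
        node_radius_um=24.0,
        node_half_thickness_um=16.0,
    )
    windows = [(40.0, 90.0), (50.0, 100.0), (30.0, 80.0)]
    cells = tuple(
        CellProgram(
            "PENETRATE_AND_EXIT",
            start_um=(25.0, 64.0 + 28.0, junctions[i][1]),
            node_index=i,
            entry_time_min=w[0],
            exit_time_min=w[1],
        )
        for i, w in enumerate(windows)
    )
    spec = SceneSpec(
        calibration=CAL,
        shape=(24, 128, 256),
        n_frames=12,
        seed=_seed(seed, 900),
        network=net,
        cells=cells,
        noise=noise,
    )
    return spec, windows


def penetration_timing(seed: int, noise: NoiseSpec = NOISE_FREE) -> dict:
    """Worst-case |recovered − programmed| ENTER/EXIT timing error, frames."""
    spec, windows = penetration_scene(seed, noise)
    series, _ = render_scene(spec)
    res = analyze_series(series)
    errors = []
    matched = 0
    annotated = sorted(res.annotated, key=lambda a: a.track.objects[0].centroid_um[2])
    for ann, (entry, exit_) in zip(annotated, windows):
        ev = ann.events
        enters = ev.loc[ev["event"] == "ENTER", "time_min"].tolist()
        exits = ev.loc[ev["event"] == "EXIT", "time_min"].tolist()
        if enters and exits:
            matched += 1
            errors.append(abs(enters[0] - entry) / CAL.dt_min)
            errors.append(abs(exits[0] - exit_) / CAL.dt_min)
    return {"value": max(errors) if errors else float("inf"), "n": matched}


# ---------------------------------------------------------------------------
# perturbation comparison


def perturbation_velocity_drop(
    seed: int,
    n_per_group: int = 20,
    control_speed: float = 0.40,
    speed_factor: float = 0.30,
    speed_sd: float = 0.08,
) -> dict:
    """Percent decrease in cohort mean speed under a programmed slowdown.

    Emulates the cohort comparison of untreated cells against cells whose
    translocation speed is reduced to 30% (a 70% velocity decrease, as seen
    for CD44-overexpressing cells); cohorts are otherwise identical.
    """
    control = matrigel_cohort_scenes(
        _seed(seed, 1000), n_per_group, control_speed, speed_sd
    )
    perturbed = matrigel_cohort_scenes(
        _seed(seed, 1001), n_per_group, control_speed * speed_factor, speed_sd
    )
    tracks_a, _ = pooled_tracks(control)
    tracks_b, _ = pooled_tracks(perturbed)
    cohort_a, cohort_b = compare_cohorts(tracks_a, tracks_b, "control", "perturbed")
    comp = cohort_a.comparisons[0]
    return {
        "value": float(comp["percent_change"]),
        "n": cohort_a.n + cohort_b.n,
        "p_value": comp["p_value"],
    }


SUITES = {
    "velocity": lambda seed: {"approach": approach_velocity_recovery(seed)},
    "along": lambda seed: {"along_network": along_velocity_recovery(seed)},
    "decay": lambda seed: {c: decay_recovery(seed, c) for c in DECAY_SCHEDULES},
    "contact": lambda seed: {"near_band": near_band_adhesion(seed)},
    "far": lambda seed: {"far_band": far_band_nontranslocation(seed)},
    "detach": lambda seed: {"detachment": detachment_rate(seed)},
    "penetration": lambda seed: {"timing": penetration_timing(seed)},
    "perturbation": lambda seed: {"velocity_drop": perturbation_velocity_drop(seed)},
}
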