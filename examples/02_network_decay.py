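"""Measure endothelial-network disassembly as percent surface-area decrease.

Programs a reticulated lattice network with the retained-volume schedule of
a cancer-cell overlay (69% at 24 h, 58% at 48 h relative to the 4-h
reference), renders and re-segments it, reconstructs faceted surfaces by
marching cubes and reports the percent decrease per frame.
"""

from transvasc.experiments import CAL, lattice_network
from transvasc.netmetrics import build_network_model, decay_report
from transvasc.scene import SceneSpec, render_scene
from transvasc.segmentation import segment_network

schedule = ((240.0, 1.0), (1440.0, 0.69), (2880.0, 0.58))
spec = SceneSpec(
    calibration=CAL,
    shape=(12, 400, 400),
    n_frames=3,
    seed=3,
    network=lattice_network(),
    decay_schedule=schedule,
    frame_times_min=tuple(t for t, _ in schedule),
)
series, truth = render_scene(spec)
models = [
    build_network_model(
        segment_network(series.frame(t, "network"), CAL, time_min=float(series.times_min[t])),
        exclude_detached=False,
    )
    for t in range(series.n_frames)
]
report = decay_report(models, reference_time_min=240.0)
print(report.frames.round(2).to_string(index=False))
print("percent_decrease is 100*(1 - area/area_4h); the 24/48-h values track")
print("the programmed 31%/42% loss to within the faceting bias (~1 point).")
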