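"""Track a directed cohort and recover its programmed approach velocity.

Ten cells are programmed to translocate toward a distant network with
per-frame step lengths drawn from Normal(0.40, 0.08) μm/min x 10 min; the
pipeline segments, links 3D centroid tracks and reports per-track mean
speeds.
"""

import numpy as np

from transvasc.experiments import matrigel_cohort_scenes, pooled_tracks

scenes = matrigel_cohort_scenes(seed=5, n_cells=10, speed_mean=0.40, speed_sd=0.08)
tracks, _ = pooled_tracks(scenes)
speeds = [tr.mean_speed_um_min for tr in tracks]
for tr in tracks[:3]:
    print(
        f"track {tr.track_id}: {len(tr)} frames, mean speed "
        f"{tr.mean_speed_um_min:.3f} um/min, persistence {tr.persistence:.2f}"
    )
print(f"cohort: n={len(speeds)}, mean={np.mean(speeds):.3f} +/- {np.std(speeds, ddof=1):.3f} um/min")
print("The cohort mean recovers the programmed 0.40 um/min within a few percent;")
print("persistence near 1 reflects the directed (non-random) motion program.")
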