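"""Render a small synthetic two-channel scene and segment both channels.

Builds a Y-shaped endothelial network plus one cancer cell, renders it with
realistic noise, then runs the bitmap (network) and threshold (cell)
segmenters and compares the recovered masks against the generator's ground
truth.
"""

import numpy as np

from transvasc import (
    CellProgram,
    NetworkSpec,
    SceneSpec,
    render_scene,
    segment_cells,
    segment_network,
)
from transvasc.io import Calibration

network = NetworkSpec(
    junctions_um=((64.0, 64.0), (64.0, 8.0), (8.0, 96.0), (120.0, 96.0)),
    edges=((0, 1), (0, 2), (0, 3)),
)
spec = SceneSpec(
    calibration=Calibration(n_z=16),
    shape=(16, 128, 128),
    n_frames=1,
    seed=7,
    network=network,
    cells=(CellProgram("STATIONARY", start_um=(20.0, 100.0, 40.0)),),
)
series, truth = render_scene(spec)

mask = segment_network(series.frame(0, "network"), spec.calibration)
inter = (mask.mask & truth.network_masks[0]).sum()
union = (mask.mask | truth.network_masks[0]).sum()
print(f"network mask: {mask.voxel_count} voxels, Jaccard vs truth = {inter/union:.3f}")

cells = segment_cells(series.frame(0, "cells"), spec.calibration)
true_c = truth.table.iloc[0][["z_um", "y_um", "x_um"]].to_numpy(float)
err = np.linalg.norm(cells[0].centroid_um - true_c)
print(f"{len(cells)} cell object(s); centroid error = {err:.2f} um")
print("A Jaccard near 1 and sub-voxel centroid error mean the default Otsu")
print("segmentation recovers the rendered geometry essentially exactly.")
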