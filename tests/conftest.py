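import numpy as np
import pytest

from transvasc.io import Calibration
from transvasc.scene import CellProgram, NetworkSpec, NoiseSpec, SceneSpec

#: standard test calibration: 1-μm lateral pixels, 2.5-μm sections, 10-min frames
CAL = Calibration(dx_um=1.0, dy_um=1.0, dz_um=2.5, dt_min=10.0, n_z=8)

NOISE_FREE = NoiseSpec(gaussian_sd=0.0, poisson=False)


def y_network(plane_z_um: float = 12.5) -> NetworkSpec:
    """Three branches meeting in one degree-3 junction."""
    return NetworkSpec(
        junctions_um=((64.0, 64.0), (64.0, 8.0), (8.0, 96.0), (120.0, 96.0)),
        edges=((0, 1), (0, 2), (0, 3)),
        plane_z_um=plane_z_um,
    )


def small_scene(
    cells=(),
    n_frames: int = 4,
    seed: int = 5,
    noise: NoiseSpec = NOISE_FREE,
    shape=(16, 128, 128),
    network: NetworkSpec | None = None,
    **kwargs,
) -> SceneSpec:
    return SceneSpec(
        calibration=Calibration(dx_um=1.0, dy_um=1.0, dz_um=2.5, dt_min=10.0, n_z=shape[0]),
        shape=shape,
        n_frames=n_frames,
        seed=seed,
        network=network or y_network(),
        cells=tuple(cells),
        noise=noise,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def ball_mask(radius_vox: float, shape, center=None, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Rasterized ellipsoid: physical radius radius_vox*spacing[1] μm."""
    zz, yy, xx = np.indices(shape).astype(float)
    if center is None:
        center = [(s - 1) / 2 for s in shape]
    sz, sy, sx = spacing
    r_um = radius_vox * sy
    return (
        ((zz - center[0]) * sz) ** 2
        + ((yy - center[1]) * sy) ** 2
        + ((xx - center[2]) * sx) ** 2
    ) <= r_um**2
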