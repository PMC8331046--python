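"""Segmentation contracts: gap preservation, threshold monotonicity,
ground-truth recovery, spline outlines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transvasc.io import Calibration
from transvasc.scene import CellProgram, NoiseSpec, render_scene
from transvasc.segmentation import default_min_voxels, segment_cells, segment_network

from conftest import CAL, small_scene


def _shoelace(poly):
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(y[:-1], x[1:]) - np.dot(y[1:], x[:-1]))


class TestSegmentNetwork:
    def test_noise_free_mask_equals_ground_truth(self):
        spec = small_scene(n_frames=1)
        series, truth = render_scene(spec)
        mask = segment_network(series.frame(0, "network"), spec.calibration)
        np.testing.assert_array_equal(mask.mask, truth.network_masks[0])

    def test_uniform_zero_frame_warns_and_is_empty(self):
        grid = np.zeros((4, 8, 8))
        with pytest.warns(UserWarning, match="all-background"):
            mask = segment_network(grid, CAL)
        assert mask.voxel_count == 0

    def test_ring_interior_stays_background(self):
        # gap preservation: a hollow ring keeps its hole
        grid = np.full((3, 64, 64), 10.0)
        yy, xx = np.indices((64, 64))
        r = np.hypot(yy - 32, xx - 32)
        ring = (r >= 10) & (r <= 20)
        grid[1][ring] = 200.0
        mask = segment_network(grid, CAL, min_component_voxels=1)
        assert mask.mask[1, 32, 32] == False  # noqa: E712
        assert mask.mask[1][ring].all()

    def test_euler_characteristic_of_annulus_preserved(self):
        from skimage.measure import euler_number

        grid = np.full((1, 64, 64), 10.0)
        yy, xx = np.indices((64, 64))
        r = np.hypot(yy - 32, xx - 32)
        ring = (r >= 8) & (r <= 16)
        grid[0][ring] = 200.0
        mask = segment_network(grid, CAL, min_component_voxels=1)
        assert euler_number(mask.mask[0], connectivity=2) == euler_number(ring, connectivity=2)

    @given(t1=st.integers(20, 120), dt=st.integers(1, 80))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_raising_fixed_threshold_never_adds_voxels(self, t1, dt):
        rng = np.random.default_rng(42)
        grid = rng.uniform(0, 255, size=(4, 16, 16))
        lo = segment_network(grid, CAL, threshold_mode=float(t1), min_component_voxels=1)
        hi = segment_network(grid, CAL, threshold_mode=float(t1 + dt), min_component_voxels=1)
        assert not (hi.mask & ~lo.mask).any()

    def test_small_components_removed(self):
        grid = np.full((4, 32, 32), 10.0)
        grid[1, 4, 4] = 200.0  # single-voxel speck
        mask = segment_network(grid, CAL)
        assert mask.voxel_count == 0
        assert default_min_voxels(CAL) == round(4 / 3 * np.pi * 125 / 2.5)


class TestSegmentCells:
    def test_single_sphere_recovered_with_accurate_centroid(self):
        cell = CellProgram("STATIONARY", start_um=(20.0, 96.0, 32.0))
        spec = small_scene([cell], n_frames=1)
        series, truth = render_scene(spec)
        objs = segment_cells(series.frame(0, "cells"), spec.calibration)
        assert len(objs) == 1
        true_centroid = truth.table.iloc[0][["z_um", "y_um", "x_um"]].to_numpy(float)
        err = np.linalg.norm(objs[0].centroid_um - true_centroid)
        assert err <= 0.5 * max(spec.calibration.dx_um, spec.calibration.dz_um)
        # voxel-perfect recovery on a noise-free scene
        vox = set(map(tuple, objs[0].voxels))
        true_vox = set(map(tuple, np.argwhere(truth.cell_labels[0] > 0)))
        assert vox == true_vox

    def test_two_separated_cells_are_disjoint_objects(self):
        cells = [
            CellProgram("STATIONARY", start_um=(20.0, 96.0, 30.0)),
            CellProgram("STATIONARY", start_um=(20.0, 96.0, 95.0)),
        ]
        spec = small_scene(cells, n_frames=1)
        series, _ = render_scene(spec)
        objs = segment_cells(series.frame(0, "cells"), spec.calibration)
        assert len(objs) == 2
        assert not (set(map(tuple, objs[0].voxels)) & set(map(tuple, objs[1].voxels)))

    def test_noisy_jaccard_at_default_settings(self):
        cell = CellProgram("STATIONARY", start_um=(20.0, 96.0, 32.0))
        spec = small_scene([cell], n_frames=1, noise=NoiseSpec())
        series, truth = render_scene(spec)
        objs = segment_cells(series.frame(0, "cells"), spec.calibration)
        assert len(objs) == 1
        got = set(map(tuple, objs[0].voxels))
        want = set(map(tuple, np.argwhere(truth.cell_labels[0] > 0)))
        jaccard = len(got & want) / len(got | want)
        assert jaccard >= 0.9

    def test_contour_area_close_to_pixel_area_with_light_smoothing(self):
        from transvasc.segmentation import SplineParams

        cell = CellProgram("STATIONARY", start_um=(20.0, 64.0, 64.0))
        spec = small_scene([cell], n_frames=1)
        series, _ = render_scene(spec)
        objs = segment_cells(
            series.frame(0, "cells"),
            spec.calibration,
            spline_params=SplineParams(smoothing=0.0, n_points=512),
        )
        obj = objs[0]
        kz = obj.z_sections[len(obj.z_sections) // 2]  # equatorial section
        poly = obj.contours[kz]
        section = np.zeros(spec.shape[1:], bool)
        sec_vox = obj.voxels[obj.voxels[:, 0] == kz]
        section[sec_vox[:, 1], sec_vox[:, 2]] = True
        pixel_area = section.sum() * spec.calibration.dx_um * spec.calibration.dy_um
        assert _shoelace(poly) == pytest.approx(pixel_area, rel=0.02)

    def test_contours_are_closed(self):
        cell = CellProgram("STATIONARY", start_um=(20.0, 64.0, 64.0))
        spec = small_scene([cell], n_frames=1)
        series, _ = render_scene(spec)
        obj = segment_cells(series.frame(0, "cells"), spec.calibration)[0]
        for poly in obj.contours.values():
            np.testing.assert_allclose(poly[0], poly[-1])

    def test_empty_frame_gives_empty_list(self):
        assert segment_cells(np.zeros((4, 8, 8)), CAL) == []
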