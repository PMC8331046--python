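"""Generator contracts: determinism, decay accounting, motion programs,
ground-truth/render consistency."""

import numpy as np
import pytest

from transvasc.io import Calibration
from transvasc.scene import (
    CellProgram,
    GenerationError,
    InvalidScheduleError,
    NoiseSpec,
    build_network,
    make_cohort,
    render_scene,
    scene_spec_from_dict,
    scene_spec_to_dict,
)
from transvasc.netmetrics import skeletonize_network

from conftest import NOISE_FREE, small_scene, y_network


class TestBuildNetwork:
    def test_constant_schedule_means_identical_masks(self):
        spec = small_scene(n_frames=3)
        masks = build_network(spec)
        assert (masks[0] == masks[1]).all() and (masks[1] == masks[2]).all()

    def test_decay_voxel_count_exact(self):
        # programmed retention 0.72 at the last frame: count must match to
        # the rounding of round(f * N0)
        spec = small_scene(
            n_frames=3,
            decay_schedule=((0.0, 1.0), (20.0, 0.72)),
        )
        masks = build_network(spec)
        n0 = masks[0].sum()
        assert abs(masks[2].sum() - round(0.72 * n0)) <= 1
        # interpolated mid frame
        assert abs(masks[1].sum() - round(0.86 * n0)) <= 1

    def test_retained_fraction_monotone(self):
        spec = small_scene(n_frames=4, decay_schedule=((0.0, 1.0), (30.0, 0.4)))
        masks = build_network(spec)
        counts = masks.reshape(4, -1).sum(axis=1)
        assert (np.diff(counts) <= 0).all()

    def test_increasing_schedule_rejected(self):
        spec = small_scene(decay_schedule=((0.0, 0.5), (10.0, 0.9)))
        with pytest.raises(InvalidScheduleError):
            build_network(spec)

    def test_out_of_range_fraction_rejected(self):
        spec = small_scene(decay_schedule=((0.0, 1.2),))
        with pytest.raises(InvalidScheduleError):
            build_network(spec)

    def test_y_network_has_one_degree3_junction(self):
        spec = small_scene()
        masks = build_network(spec)
        graph = skeletonize_network(masks[0], spec.calibration)
        assert len(graph.node_ids) == 1
        assert graph.graph.degree(("J", graph.node_ids[0])) == 3


class TestRenderScene:
    def test_stationary_cell_frames_identical_and_centroid_constant(self):
        cell = CellProgram("STATIONARY", start_um=(20.0, 96.0, 32.0))
        spec = small_scene([cell], n_frames=3)
        series, truth = render_scene(spec)
        np.testing.assert_array_equal(series.data[0, 1], series.data[1, 1])
        g = truth.table
        assert g.groupby("cell_id")[["z_um", "y_um", "x_um"]].nunique().max().max() == 1

    def test_directed_cell_moves_at_programmed_speed(self):
        # speed_sd = 0: consecutive centers exactly v*dt apart until contact
        v = 0.3
        cell = CellProgram("DIRECTED_TO_NETWORK", start_um=(20.0, 110.0, 20.0), speed_mean=v)
        spec = small_scene([cell], n_frames=4)
        _, truth = render_scene(spec)
        steps = np.linalg.norm(np.diff(truth.centers_um[:, 0, :], axis=0), axis=1)
        assert np.allclose(steps, v * 10.0, atol=1e-9)

    def test_fixed_seed_is_byte_identical(self):
        cell = CellProgram("RANDOM_WALK", start_um=(20.0, 100.0, 40.0), speed_mean=0.2, speed_sd=0.1)
        spec = small_scene([cell], noise=NoiseSpec())
        s1, _ = render_scene(spec)
        s2, _ = render_scene(spec)
        assert s1.data.tobytes() == s2.data.tobytes()

    def test_ground_truth_voxels_are_foreground_before_noise(self):
        cell = CellProgram("STATIONARY", start_um=(20.0, 96.0, 32.0))
        spec = small_scene([cell], n_frames=2, noise=NOISE_FREE)
        series, truth = render_scene(spec)
        fg = spec.noise.foreground
        assert (series.data[0, 0][truth.network_masks[0]] == fg).all()
        assert (series.data[0, 1][truth.cell_labels[0] > 0] == fg).all()

    def test_anisotropy_honesty_of_rendered_sphere(self):
        # 30-μm body: 30/dz = 12 sections axially, 30/dx = 30 px laterally
        cell = CellProgram("STATIONARY", start_um=(20.0, 64.0, 64.0))
        spec = small_scene([cell], n_frames=1, shape=(20, 128, 128))
        _, truth = render_scene(spec)
        vz, vy, vx = np.nonzero(truth.cell_labels[0])
        assert vz.max() - vz.min() + 1 in (12, 13)
        assert vx.max() - vx.min() + 1 in (30, 31)

    def test_cell_leaving_grid_names_program(self):
        cell = CellProgram("STATIONARY", start_um=(20.0, 5.0, 5.0))
        spec = small_scene([cell])
        with pytest.raises(GenerationError, match="program 0"):
            render_scene(spec)

    def test_spec_yaml_round_trip(self):
        cell = CellProgram("STATIONARY", start_um=(20.0, 96.0, 32.0))
        spec = small_scene([cell])
        back = scene_spec_from_dict(scene_spec_to_dict(spec))
        assert back == spec


class TestMakeCohort:
    def test_exact_reacher_count(self):
        scenes = make_cohort(Calibration(), 100, 0.68, (0.0, 65.0), seed=9)
        kinds = [c.kind for s in scenes for c in s.cells]
        assert len(kinds) == 100
        assert sum(k == "DIRECTED_TO_NETWORK" for k in kinds) == 68

    def test_fraction_zero_no_cell_contacts(self):
        scenes = make_cohort(
            Calibration(), 8, 0.0, (10.0, 60.0), seed=9, cells_per_scene=8, noise=NOISE_FREE
        )
        series, truth = render_scene(scenes[0])
        # ground truth: no cell voxel ever overlaps or touches the network
        for t in range(series.n_frames):
            assert not (truth.network_masks[t] & (truth.cell_labels[t] > 0)).any()
        assert set(truth.table["state"]) == {"FREE"}

    def test_fraction_one_all_contact_by_final_frame(self):
        scenes = make_cohort(
            Calibration(), 5, 1.0, (5.0, 40.0), seed=9, cells_per_scene=5, noise=NOISE_FREE
        )
        _, truth = render_scene(scenes[0])
        last = truth.table[truth.table["time_min"] == truth.table["time_min"].max()]
        assert (last["state"] == "ON_NETWORK").all()

    def test_infeasible_band_raises(self):
        with pytest.raises(GenerationError):
            make_cohort(Calibration(), 10, 0.5, (30.0, 20.0), seed=1)
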