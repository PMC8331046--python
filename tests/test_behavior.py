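"""State classification against brute-force oracles and the event machine."""

import numpy as np

import pytest

from transvasc.behavior import (
    BehaviorParams,
    annotate_track,
    classify_frame,
    population_summary,
)
from transvasc.io import Calibration
from transvasc.segmentation import BinaryVolume, CellObject

from conftest import CAL


def cell_from_voxels(voxels, cal=CAL, oid=0, t=0.0):
    vox = np.asarray(voxels, int)
    centroid = vox.mean(axis=0) * np.asarray(cal.spacing)
    return CellObject(oid, t, vox, centroid, len(vox))


def brute_force(cell, mask: BinaryVolume):
    """Explicit overlap count + min pairwise voxel distance."""
    vz, vy, vx = cell.voxels.T
    overlap = mask.mask[vz, vy, vx].sum() / len(cell.voxels)
    net = np.argwhere(mask.mask).astype(float)
    if len(net) == 0:
        return overlap, np.inf
    cellpts = cell.voxels.astype(float)
    spacing = np.asarray(mask.calibration.spacing)
    d = np.linalg.norm(
        cellpts[:, None, :] * spacing - net[None, :, :] * spacing, axis=2
    ).min()
    if overlap > 0:
        d = 0.0
    return overlap, d


class TestClassifyFrame:
    def test_fully_inside_mask(self):
        mask = BinaryVolume(np.ones((4, 8, 8), bool), CAL)
        cell = cell_from_voxels([(1, 2, 2), (1, 2, 3)])
        state, d, f = classify_frame(cell, mask)
        assert state == "INSIDE_NETWORK" and f == 1.0 and d == 0.0

    def test_far_cell_distance_matches_oracle(self):
        arr = np.zeros((8, 128, 128), bool)
        arr[3:5, 10:14, :] = True
        mask = BinaryVolume(arr, CAL)
        cell = cell_from_voxels([(4, 110, 64)])
        state, d, f = classify_frame(cell, mask)
        _, d_oracle = brute_force(cell, mask)
        assert state == "FREE"
        assert d == pytest.approx(d_oracle, abs=1e-9)
        assert d == pytest.approx(110 - 13, abs=1e-9)

    def test_half_overlap_is_inside_at_default_threshold(self):
        # boundary inclusive: exactly 50% overlap counts as inside
        arr = np.zeros((4, 16, 16), bool)
        arr[1, :8, :] = True
        mask = BinaryVolume(arr, CAL)
        cell = cell_from_voxels([(1, 7, 3), (1, 8, 3)])
        state, _, f = classify_frame(cell, mask)
        assert f == 0.5 and state == "INSIDE_NETWORK"

    def test_adjacent_voxel_is_contact(self):
        arr = np.zeros((4, 16, 16), bool)
        arr[1, 5, 5] = True
        mask = BinaryVolume(arr, CAL)
        cell = cell_from_voxels([(1, 5, 6)])
        state, d, _ = classify_frame(cell, mask)
        assert d == pytest.approx(1.0) and state == "ON_NETWORK"

    def test_empty_mask_gives_free_with_infinite_distance(self):
        mask = BinaryVolume(np.zeros((4, 8, 8), bool), CAL)
        cell = cell_from_voxels([(1, 2, 2)])
        state, d, f = classify_frame(cell, mask)
        assert state == "FREE" and np.isinf(d) and f == 0.0

    def test_agrees_with_brute_force_on_100_random_cases(self):
        rng = np.random.default_rng(77)
        params = BehaviorParams()
        for _ in range(100):
            arr = rng.random((5, 14, 14)) < 0.12
            mask = BinaryVolume(arr, CAL)
            n_vox = int(rng.integers(1, 9))
            vox = np.unique(
                np.column_stack(
                    [rng.integers(0, 5, n_vox), rng.integers(0, 14, n_vox), rng.integers(0, 14, n_vox)]
                ),
                axis=0,
            )
            cell = cell_from_voxels(vox)
            state, d, f = classify_frame(cell, mask, params)
            f_oracle, d_oracle = brute_force(cell, mask)
            assert f == pytest.approx(f_oracle)
            assert d == pytest.approx(d_oracle, abs=1e-9)
            if arr.any():
                if f_oracle >= 0.5:
                    assert state == "INSIDE_NETWORK"
                elif d_oracle <= 1.0:
                    assert state == "ON_NETWORK"
                else:
                    assert state == "FREE"


def fake_track(n, dt=10.0, step=(0.0, 0.0, 0.0)):
    from transvasc.tracking import Track

    tr = Track(track_id=0)
    step = np.asarray(step, float)
    for i in range(n):
        vox = np.zeros((1, 3), int)
        c = np.array([5.0, 50.0, 50.0]) + step * i
        tr.append(i * dt, CellObject(0, i * dt, vox, c, 1))
    return tr


class TestAnnotateTrack:
    def test_approaching_assigned_on_monotone_descent(self):
        tr = fake_track(6)
        labels = ["FREE"] * 4 + ["ON_NETWORK"] * 2
        dists = [40.0, 30.0, 20.0, 10.0, 0.0, 0.0]
        ann = annotate_track(tr, labels, dists)
        assert ann.states[:4] == ["APPROACHING"] * 4
        assert ann.has_event("CONTACT")

    def test_far_stationary_track_stays_free_no_events(self):
        tr = fake_track(5)
        ann = annotate_track(tr, ["FREE"] * 5, [80.0] * 5)
        assert set(ann.states) == {"FREE"}
        assert len(ann.events) == 0

    def test_adhesion_after_persistent_contact_no_detach(self):
        tr = fake_track(8)
        labels = ["FREE", "FREE"] + ["ON_NETWORK"] * 6
        dists = [20.0, 10.0] + [0.0] * 6
        ann = annotate_track(tr, labels, dists)
        assert ann.has_event("ADHESION") and not ann.has_event("DETACH")
        # adhesion requires prior contact
        ev = ann.events.set_index("event")["time_min"]
        assert ev["CONTACT"] <= ev["ADHESION"]

    def test_detach_after_adhesion(self):
        tr = fake_track(10)
        labels = ["ON_NETWORK"] * 4 + ["FREE"] * 6
        dists = [0.0] * 4 + [30.0] * 6
        ann = annotate_track(tr, labels, dists)
        assert ann.has_event("DETACH")

    def test_enter_exit_pairing_and_ordering(self):
        tr = fake_track(7)
        labels = ["ON_NETWORK", "INSIDE_NETWORK", "INSIDE_NETWORK", "ON_NETWORK",
                  "INSIDE_NETWORK", "ON_NETWORK", "ON_NETWORK"]
        dists = [0.0] * 7
        ann = annotate_track(tr, labels, dists)
        ev = ann.events
        enters = ev.loc[ev["event"] == "ENTER", "time_min"].tolist()
        exits = ev.loc[ev["event"] == "EXIT", "time_min"].tolist()
        assert enters == [10.0, 40.0]
        assert exits == [30.0, 50.0]
        assert all(en < ex for en, ex in zip(enters, exits))

    def test_no_inside_frame_without_prior_enter(self):
        tr = fake_track(5)
        labels = ["INSIDE_NETWORK"] * 2 + ["ON_NETWORK"] * 3
        ann = annotate_track(tr, labels, [0.0] * 5)
        ev = ann.events
        first_enter = ev.loc[ev["event"] == "ENTER", "time_min"].min()
        inside_times = [t for t, s in zip(tr.times_min, ann.states) if s == "INSIDE_NETWORK"]
        assert first_enter <= min(inside_times)


class TestPopulationSummary:
    def test_single_free_track_counts_zero_of_one(self):
        tr = fake_track(5)
        ann = annotate_track(tr, ["FREE"] * 5, [40.0] * 5)
        summary = population_summary([ann])
        near = summary[summary["bin"] == "near"].iloc[0]
        assert near["n"] == 1 and near["adhered_fraction"] == 0.0

    def test_empty_bin_reports_nan_not_zero(self):
        tr = fake_track(5)
        ann = annotate_track(tr, ["FREE"] * 5, [40.0] * 5)
        summary = population_summary([ann])
        far = summary[summary["bin"] == "far"].iloc[0]
        assert far["n"] == 0 and np.isnan(far["adhered_fraction"])

    def test_intermediate_band_reported_separately(self):
        tr = fake_track(5)
        ann = annotate_track(tr, ["FREE"] * 5, [70.0] * 5)
        summary = population_summary([ann])
        assert summary[summary["bin"] == "mid"].iloc[0]["n"] == 1

    def test_nontranslocating_uses_displacement_threshold(self):
        still = annotate_track(fake_track(5), ["FREE"] * 5, [90.0] * 5)
        mover = annotate_track(
            fake_track(5, step=(0.0, 10.0, 0.0)), ["FREE"] * 5, [90.0] * 5
        )
        summary = population_summary([still, mover])
        far = summary[summary["bin"] == "far"].iloc[0]
        assert far["nontranslocating_fraction"] == pytest.approx(0.5)
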