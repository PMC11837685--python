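"""COP moment balance, COM weighted centroid, gap handling, discard
logic and the CSV ingestion formats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swayclass.kinematics import (KINECT_JOINTS, ForcePlateRecord, Segment,
                                  SegmentModel, SkeletonSequence, SwayTrial,
                                  compute_com, compute_cop,
                                  discard_invalid_trials, read_board_csv,
                                  read_skeleton_csv)
from swayclass.synthetic import canonical_pose


def _record(loads, width=0.4, depth=0.24):
    loads = np.atleast_2d(np.asarray(loads, dtype=float))
    return ForcePlateRecord(t=np.arange(len(loads)) / 100.0, loads=loads,
                            board_width=width, board_depth=depth)


class TestComputeCop:
    def test_equal_loads_give_origin(self):
        trial = compute_cop(_record([10.0, 10.0, 10.0, 10.0]))
        assert trial.ap[0] == 0.0 and trial.ml[0] == 0.0

    def test_all_load_on_top_right_corner(self):
        trial = compute_cop(_record([0.0, 50.0, 0.0, 0.0]))
        assert trial.ap[0] == pytest.approx(0.12)   # +D/2
        assert trial.ml[0] == pytest.approx(0.20)   # +W/2

    def test_hand_computed_torque_balance(self):
        # loads (TL, TR, BL, BR) = (10, 20, 30, 40) N, W=0.4 m, D=0.24 m
        trial = compute_cop(_record([10.0, 20.0, 30.0, 40.0]))
        assert trial.ml[0] == pytest.approx(0.2 * (60 - 40) / 100)   # 0.04
        assert trial.ap[0] == pytest.approx(0.12 * (30 - 70) / 100)  # -0.048

    def test_zero_total_load_is_no_contact(self):
        with pytest.raises(ValueError, match="no contact"):
            compute_cop(_record([0.0, 0.0, 0.0, 0.0]))

    @given(st.lists(st.tuples(*[st.floats(0.0, 1000.0)] * 4), min_size=1,
                    max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_cop_stays_inside_board(self, loads):
        loads = np.asarray(loads) + 1e-6  # ensure contact
        trial = compute_cop(_record(loads))
        assert np.all(np.abs(trial.ml) <= 0.2 + 1e-12)
        assert np.all(np.abs(trial.ap) <= 0.12 + 1e-12)


class TestComputeCom:
    def test_coincident_joints_give_that_point(self):
        p = np.array([0.3, 1.2, -0.1])
        joints = np.tile(p, (5, 25, 1))
        seq = SkeletonSequence(t=np.arange(5) / 30.0, joints=joints)
        trial = compute_com(seq)
        assert np.allclose(trial.ml, p[0]) and np.allclose(trial.ap, p[2])

    def test_two_segment_weighted_centroid_by_hand(self):
        model = SegmentModel((
            Segment("a", "SpineBase", "Head", 0.6, 0.0),   # center at prox
            Segment("b", "HipLeft", "KneeLeft", 0.4, 1.0),  # center at dist
        ))
        joints = np.zeros((1, 25, 3))
        idx = {n: i for i, n in enumerate(KINECT_JOINTS)}
        joints[0, idx["KneeLeft"]] = (1.0, 0.0, 0.0)
        seq = SkeletonSequence(t=[0.0], joints=joints)
        trial = compute_com(seq, model)
        assert trial.ml[0] == pytest.approx(0.4)  # 0.6*0 + 0.4*1
        assert trial.ap[0] == pytest.approx(0.0)

    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SegmentModel((
                Segment("a", "SpineBase", "Head", 0.58, 0.5),
                Segment("b", "HipLeft", "KneeLeft", 0.40, 0.5),
            ))

    def test_missing_joint_is_named(self):
        seq = SkeletonSequence(t=[0.0], joints=np.zeros((1, 25, 3)),
                               joint_names=tuple(f"J{i}" for i in range(25)))
        with pytest.raises(ValueError, match="SpineBase"):
            compute_com(seq)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        joints = canonical_pose()[None, :, :] + rng.normal(0, 0.02, (10, 25, 3))
        t = np.arange(10) / 30.0
        shift = np.array([0.05, -0.1, 0.2])
        a = compute_com(SkeletonSequence(t=t, joints=joints))
        b = compute_com(SkeletonSequence(t=t, joints=joints + shift))
        assert np.allclose(b.ml - a.ml, shift[0], atol=1e-12)
        assert np.allclose(b.ap - a.ap, shift[2], atol=1e-12)

    def test_short_gap_interpolated_long_gap_invalid(self):
        n = 90  # 3 s at 30 Hz
        joints = np.tile(canonical_pose(), (n, 1, 1))
        joints[:, 0, 0] = np.linspace(0.0, 1.0, n)  # SpineBase m-l ramp
        joints[10:13, :, :] = np.nan          # 0.1 s gap: interpolable
        joints[40:70, :, :] = np.nan          # 1.0 s gap: too long
        seq = SkeletonSequence(t=np.arange(n) / 30.0, joints=joints)
        trial = compute_com(seq, max_gap=0.5)
        assert trial.valid[10:13].all()       # filled
        assert not trial.valid[40:70].any()   # flagged invalid
        ramp = np.linspace(0.0, 1.0, n)
        seg = SegmentModel.default().segments[0]
        assert np.isfinite(trial.ml[10:13]).all()


class TestDiscard:
    def _trial(self, valid):
        n = len(valid)
        return SwayTrial(subject_id="S1", group_label="PD", trial_index=0,
                         parameter="COM", t=np.arange(n) / 30.0,
                         ap=np.zeros(n), ml=np.zeros(n), valid=valid)

    def test_fully_tracked_trials_survive(self):
        trials = [self._trial(np.ones(30, dtype=bool)) for _ in range(3)]
        kept, log = discard_invalid_trials(trials)
        assert len(kept) == 3 and log == []

    def test_half_tracked_trial_discarded_and_logged(self):
        valid = np.zeros(30, dtype=bool)
        valid[:15] = True
        kept, log = discard_invalid_trials(
            [self._trial(valid)], min_valid_fraction=0.9
        )
        assert kept == []
        assert log[0]["subject_id"] == "S1"
        assert log[0]["valid_fraction"] == pytest.approx(0.5)


class TestSegmentModelAndReaders:
    def test_default_table_sums_to_one(self):
        model = SegmentModel.default()
        assert sum(s.mass_fraction for s in model.segments) == pytest.approx(1.0)
        joints = {j for s in model.segments for j in (s.proximal, s.distal)}
        assert joints <= set(KINECT_JOINTS)

    def test_board_csv_roundtrip(self, tmp_path):
        df = pd.DataFrame({
            "t": [0.0, 0.01], "f_tl": [10.0, 11.0], "f_tr": [20.0, 19.0],
            "f_bl": [30.0, 30.0], "f_br": [40.0, 40.0],
        })
        path = tmp_path / "board.csv"
        df.to_csv(path, index=False)
        rec = read_board_csv(path)
        assert np.allclose(rec.loads[0], [10, 20, 30, 40])
        path.write_text("t\n0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_board_csv(path)

    def test_skeleton_csv_roundtrip(self, tmp_path):
        n = 4
        rng = np.random.default_rng(1)
        joints = rng.normal(size=(n, 25, 3))
        cols = {"t": np.arange(n) / 30.0}
        for j, name in enumerate(KINECT_JOINTS):
            for a, axis in enumerate("xyz"):
                cols[f"{name}_{axis}"] = joints[:, j, a]
        path = tmp_path / "skel.csv"
        pd.DataFrame(cols).to_csv(path, index=False)
        seq = read_skeleton_csv(path)
        assert np.allclose(seq.joints, joints)
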