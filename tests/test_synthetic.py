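"""Synthetic cohort generator: spectral contract, raw-representation
round trips, dropout statistics, seed determinism."""

import numpy as np
import pytest
from scipy.signal import welch

from swayclass.kinematics import compute_com, compute_cop
from swayclass.synthetic import (BoardGeometry, ClassSpec, CohortSpec,
                                 gen_board_loads, gen_cohort, gen_skeleton,
                                 gen_sway_trajectory)


class TestSwayTrajectory:
    def test_sample_count_is_duration_times_rate(self):
        traj = gen_sway_trajectory(ClassSpec.hc_default(), 30.0, 90.0, seed=0)
        assert traj.shape == (2700, 2)

    def test_rate_below_nyquist_bound_rejected(self):
        spec = ClassSpec("PD", band_hi=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            gen_sway_trajectory(spec, 30.0, 20.0, seed=0)

    def test_seed_determinism_byte_identical(self):
        spec = ClassSpec.pd_default()
        a = gen_sway_trajectory(spec, 10.0, 50.0, seed=123)
        b = gen_sway_trajectory(spec, 10.0, 50.0, seed=123)
        assert a.tobytes() == b.tobytes()

    def test_rms_amplitude_matches_spec(self):
        spec = ClassSpec.hc_default()
        rng = np.random.default_rng(0)
        x = np.concatenate(
            [gen_sway_trajectory(spec, 30.0, 50.0, rng)[:, 0]
             for _ in range(40)]
        )
        assert spec.rms_amplitude * 0.9 < x.std() < spec.rms_amplitude * 1.1

    @pytest.mark.parametrize("gain,lo,hi", [(1.0, 0.8, 1.25), (4.0, 3.4, 4.7)])
    def test_welch_band_power_ratio_recovers_gain(self, gain, lo, hi):
        """Welch-PSD oracle over 200 trials: in-band power ratio between a
        banded class and the gain-1 baseline equals the band gain."""
        banded = ClassSpec("PD", band_gain=gain)
        flat = ClassSpec("HC", band_gain=1.0)
        rng = np.random.default_rng(7)

        def band_power(spec):
            acc = 0.0
            for _ in range(200):
                traj = gen_sway_trajectory(spec, 30.0, 50.0, rng)
                f, p = welch(traj[:, 1], fs=50.0, nperseg=512)
                acc += p[(f >= 1.5) & (f <= 9.5)].mean()
            return acc / 200

        ratio = band_power(banded) / band_power(flat)
        assert lo < ratio < hi


class TestBoardLoads:
    def test_center_trajectory_gives_equal_loads(self):
        traj = np.zeros((50, 2))
        rec = gen_board_loads(traj, total_weight=700.0)
        assert np.allclose(rec.loads, 175.0)

    def test_loads_sum_to_total_weight_every_sample(self):
        traj = gen_sway_trajectory(ClassSpec.hc_default(), 5.0, 100.0, seed=1)
        rec = gen_board_loads(traj, total_weight=700.0, seed=2)
        assert np.allclose(rec.loads.sum(axis=1), 700.0)
        assert rec.loads.min() >= 0

    def test_roundtrip_through_cop_formula(self):
        """Forward COP computation is the oracle for the inverse map."""
        traj = gen_sway_trajectory(ClassSpec.pd_default(), 10.0, 100.0, seed=3)
        rec = gen_board_loads(traj, seed=4)
        trial = compute_cop(rec)
        geom = BoardGeometry()
        err = max(np.abs(trial.ap - traj[:, 0]).max() / geom.depth,
                  np.abs(trial.ml - traj[:, 1]).max() / geom.width)
        assert err < 1e-9

    def test_trajectory_outside_board_rejected(self):
        traj = np.array([[0.0, 0.4]])  # 40 cm medio-lateral: off the board
        with pytest.raises(ValueError, match="outside the sensor rectangle"):
            gen_board_loads(traj)


class TestSkeleton:
    def test_shape_25_joints_3_coords(self):
        traj = np.zeros((40, 2))
        seq = gen_skeleton(traj, seed=0)
        assert seq.joints.shape == (40, 25, 3)

    def test_zero_trajectory_zero_jitter_is_static(self):
        seq = gen_skeleton(np.zeros((30, 2)), jitter_std=0.0)
        assert np.ptp(seq.joints, axis=0).max() == 0.0
        com = compute_com(seq)
        assert np.ptp(com.ml) == 0.0 and np.ptp(com.ap) == 0.0

    def test_exact_com_roundtrip_without_jitter(self):
        traj = gen_sway_trajectory(ClassSpec.hc_default(), 5.0, 30.0, seed=5)
        com = compute_com(gen_skeleton(traj, jitter_std=0.0))
        assert np.abs((com.ml - com.ml.mean())
                      - (traj[:, 1] - traj[:, 1].mean())).max() < 1e-12
        assert np.abs((com.ap - com.ap.mean())
                      - (traj[:, 0] - traj[:, 0].mean())).max() < 1e-12

    def test_com_roundtrip_with_jitter_correlates(self):
        traj = gen_sway_trajectory(ClassSpec.hc_default(), 10.0, 30.0, seed=6)
        com = compute_com(gen_skeleton(traj, seed=7))
        assert np.corrcoef(com.ml, traj[:, 1])[0, 1] > 0.99


class TestCohort:
    def test_group_sizes_follow_spec(self):
        cohort = gen_cohort(CohortSpec(n_pd=18, n_hc=15, trials_per_subject=1,
                                       trial_duration=1.0, seed=0))
        assert len(cohort.group("PD")) == 18
        assert len(cohort.group("HC")) == 15

    def test_zero_dropout_keeps_all_trials(self):
        cohort = gen_cohort(
            CohortSpec(n_pd=3, n_hc=3, trial_duration=1.0, seed=1),
            ClassSpec("PD", trial_dropout_prob=0.0),
            ClassSpec("HC", trial_dropout_prob=0.0),
        )
        assert all(len(s.trials) == 10 for s in cohort.subjects)
        assert cohort.dropout_log == []

    def test_dropout_fraction_matches_binomial_expectation(self):
        """1000 simulated PD subjects: mean discard fraction ~ 0.10."""
        cohort = gen_cohort(
            CohortSpec(n_pd=1000, n_hc=1, trial_duration=1.0, seed=2),
            ClassSpec.pd_default(),
            ClassSpec("HC", trial_dropout_prob=0.0),
        )
        kept = sum(len(s.trials) for s in cohort.group("PD"))
        frac = 1.0 - kept / 10000.0
        assert abs(frac - 0.10) < 0.01

    def test_seed_determinism_of_cohort(self):
        spec = CohortSpec(n_pd=2, n_hc=2, trials_per_subject=2,
                          trial_duration=2.0, seed=11)
        a, b = gen_cohort(spec), gen_cohort(spec)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.subject_id == sb.subject_id
            assert sa.band_gain_multiplier == sb.band_gain_multiplier
            for ta, tb in zip(sa.trials, sb.trials):
                assert ta.cop.ap.tobytes() == tb.cop.ap.tobytes()
                assert ta.com.ml.tobytes() == tb.com.ml.tobytes()

    def test_raw_trial_regeneration_is_consistent(self):
        spec = CohortSpec(n_pd=1, n_hc=1, trials_per_subject=1,
                          trial_duration=2.0, seed=3)
        cohort = gen_cohort(spec)
        subj = cohort.subjects[0]
        board, skel = cohort.raw_trial(subj.subject_id, subj.trials[0].trial_index)
        cop = compute_cop(board)
        assert np.allclose(cop.ml, subj.trials[0].cop.ml, atol=1e-12)
        board2, _ = cohort.raw_trial(subj.subject_id,
                                     subj.trials[0].trial_index)
        assert board.loads.tobytes() == board2.loads.tobytes()
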