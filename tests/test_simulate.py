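"""Stochastic simulators: stepping kinetics, clamp geometry, sampling."""

import numpy as np
import pytest

from myostep import models
from myostep.models import KBT_ROOM, expected_measured_runlength
from myostep.simulate import (
    ClampConfig,
    MotorModel,
    sample_truncated_run_lengths,
    simulate_clamp_record,
    simulate_image_stack,
    simulate_motility_trajectory,
    simulate_stepping,
)

EPS_RATE = 1e-9


def single_clock_model(kf=10.0):
    """Forward stepping only: backward and detachment rates negligible."""
    return MotorModel(
        k0f_plus=kf, df_plus=0.0, k0b_plus=EPS_RATE, db_plus=0.0,
        k0f_minus=kf, df_minus=0.0, k0b_minus=EPS_RATE, db_minus=0.0,
        kd0_plus=EPS_RATE, dk_plus=0.0, kd0_minus=EPS_RATE, dk_minus=0.0,
    )


class TestMotorModel:
    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            MotorModel(k0f_plus=-1.0)
        with pytest.raises(ValueError):
            MotorModel(step_fwd=95.0)
        with pytest.raises(ValueError):
            MotorModel(kBT=0.0)

    def test_rates_follow_branch_of_force_sign(self):
        m = MotorModel()
        kf_r, kb_r, kd_r = m.rates(+1.5)
        assert kf_r == pytest.approx(6.5 * np.exp(1.5 * 2.2 / KBT_ROOM))
        assert kb_r == pytest.approx(10.0 * np.exp(1.5 * 2.0 / KBT_ROOM))
        assert kd_r == pytest.approx(0.64 * np.exp(1.5 * 4.2 / KBT_ROOM))
        kf_a, kb_a, kd_a = m.rates(-1.5)
        assert kf_a == pytest.approx(14.6 * np.exp(-1.5 * 0.05 / KBT_ROOM))
        assert kb_a == pytest.approx(54.1 * np.exp(-1.5 * 2.4 / KBT_ROOM))
        assert kd_a == pytest.approx(2.3 * np.exp(1.5 * 1.9 / KBT_ROOM))

    def test_zero_force_is_branch_mean(self):
        m = MotorModel()
        kf, kb, kd = m.rates(0.0)
        assert kf == pytest.approx((6.5 + 14.6) / 2)
        assert kb == pytest.approx((10.0 + 54.1) / 2)
        assert kd == pytest.approx((0.64 + 2.3) / 2)

    def test_nonfinite_rates_rejected(self):
        m = MotorModel()
        with pytest.raises(ValueError, match="non-finite"):
            m.rates(1e6)


class TestStepping:
    def test_single_clock_velocity_limit(self):
        traj = simulate_stepping(single_clock_model(10.0), 0.0, 200.0, seed=0)
        v = traj.run_length / traj.duration
        assert v == pytest.approx(360.0, rel=0.05)

    def test_invariants_first_attach_last_detach(self):
        traj = simulate_stepping(MotorModel(), 1.0, 5.0, seed=1)
        assert traj.events[0][1] == "attach"
        assert traj.events[-1][1] == "detach"
        times = [t for t, _, _ in traj.events]
        assert np.all(np.diff(times) > 0)

    def test_rate_balance_force_gives_zero_net_displacement(self):
        # forward and backward clocks cross where
        # 6.5 exp(2.2 F / kBT) = 10 exp(2.0 F / kBT)
        F_bal = KBT_ROOM / 0.2 * np.log(10.0 / 6.5)
        model = MotorModel(step_bwd=36.0)  # symmetric steps isolate the rates
        rng = np.random.default_rng(7)
        disp = [simulate_stepping(model, F_bal, 10.0, seed=rng).run_length
                for _ in range(2000)]
        se = np.std(disp, ddof=1) / np.sqrt(len(disp))
        assert abs(np.mean(disp)) < 3 * se + 1e-9

    def test_step_count_ratio_matches_rate_ratio(self):
        model, F = MotorModel(), 1.5
        kf, kb, _ = model.rates(F)
        rng = np.random.default_rng(3)
        nf = nb = 0
        for _ in range(3000):
            tr = simulate_stepping(model, F, 20.0, seed=rng)
            nf += tr.n_fwd
            nb += tr.n_bwd
        ratio = nf / nb
        se = ratio * np.sqrt(1 / nf + 1 / nb)
        assert ratio == pytest.approx(kf / kb, abs=3.5 * se)

    def test_mean_duration_and_run_length_match_theory(self):
        model, F = MotorModel(), 1.5
        kf, kb, kd = model.rates(F)
        rng = np.random.default_rng(4)
        trajs = [simulate_stepping(model, F, 100.0, seed=rng) for _ in range(2000)]
        durations = np.array([t.duration for t in trajs])
        lengths = np.array([t.run_length for t in trajs])
        se_d = durations.std(ddof=1) / np.sqrt(len(trajs))
        se_l = lengths.std(ddof=1) / np.sqrt(len(trajs))
        assert durations.mean() == pytest.approx(1 / kd, abs=3.5 * se_d)
        expected_L = (model.step_fwd * kf - model.step_bwd * kb) / kd
        assert lengths.mean() == pytest.approx(expected_L, abs=3.5 * se_l)

    def test_reproducible_bit_for_bit(self):
        a = simulate_stepping(MotorModel(), 1.0, 5.0, seed=11)
        b = simulate_stepping(MotorModel(), 1.0, 5.0, seed=11)
        assert a.events == b.events


class TestClampRecord:
    def test_window_smaller_than_step_raises(self):
        with pytest.raises(ValueError, match="no run observable"):
            simulate_clamp_record(MotorModel(), ClampConfig(1.0, 20.0))

    def test_motor_free_record_is_triangular_wave(self):
        cfg = ClampConfig(1.0, 400.0, sample_rate=20000.0, noise_sigma=0.0,
                          drag_velocity=8000.0, seed=0)
        rec = simulate_clamp_record(MotorModel(), cfg, duration=1.0, attach=False)
        period = 2 * 400.0 / 8000.0
        assert rec.position.max() == pytest.approx(400.0, abs=1.0)
        assert rec.position.min() == pytest.approx(0.0, abs=1.0)
        n_period = int(period * cfg.sample_rate)
        # exact periodicity of the noiseless triangle
        assert np.allclose(rec.position[:n_period],
                           rec.position[n_period:2 * n_period], atol=1e-6)
        assert not rec.ground_truth

    def test_assistive_runs_truncated_at_window_mean_near_half_D(self):
        # true mean run length ~10x the window: measured mean approaches
        # the expectation of the censored density (close to D/2)
        D = 200.0
        model = MotorModel(
            k0f_minus=100.0, df_minus=0.0, k0b_minus=EPS_RATE, db_minus=0.0,
            kd0_minus=1.8, dk_minus=0.0,
            kd0_plus=20.0, dk_plus=0.0, attach_rate=5.0)
        cfg = ClampConfig(1.0, D, sample_rate=10000.0, noise_sigma=0.0,
                          drag_velocity=20000.0, seed=2)
        rec = simulate_clamp_record(model, cfg, duration=120.0)
        assist = [g for g in rec.ground_truth if g["force"] < 0 and not g["censored"]]
        lengths = np.array([g["pos_detach"] - g["pos_attach"] for g in assist])
        assert len(lengths) > 60
        L_true = 36.0 * 100.0 / 1.8
        expect = expected_measured_runlength(L_true, D)
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert lengths.mean() == pytest.approx(expect, abs=3.5 * se)
        assert expect == pytest.approx(D / 2, rel=0.1)
        assert any(g["truncated"] for g in assist)

    def test_resistive_durations_exponential_and_untruncated(self):
        from scipy import stats

        model = MotorModel(kd0_plus=5.0, dk_plus=0.0, attach_rate=5.0)
        cfg = ClampConfig(1.0, 400.0, sample_rate=10000.0, noise_sigma=0.0,
                          drag_velocity=20000.0, seed=3)
        rec = simulate_clamp_record(model, cfg, duration=120.0)
        resist = [g for g in rec.ground_truth
                  if g["force"] > 0 and not g["censored"] and not g["truncated"]]
        tau = np.array([g["t_detach"] - g["t_attach"] for g in resist])
        assert len(tau) > 80
        p = stats.kstest(tau, "expon", args=(0, 1 / 5.0)).pvalue
        assert p > 0.01

    def test_reproducible_bit_for_bit(self):
        cfg = ClampConfig(1.5, 400.0, sample_rate=20000.0, seed=9)
        a = simulate_clamp_record(MotorModel(), cfg, duration=2.0)
        b = simulate_clamp_record(MotorModel(), cfg, duration=2.0)
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.force, b.force)
        assert a.ground_truth == b.ground_truth


class TestMotilityTrajectory:
    def test_noiseless_positions_on_lattice(self):
        tr = simulate_motility_trajectory(100.0, 720.0, 0.05, 0.0, seed=5)
        steps = np.diff(np.unique(tr.x))
        assert np.allclose(steps % 36.0, 0.0, atol=1e-9) or np.allclose(
            steps % 36.0, 36.0, atol=1e-9)
        assert np.allclose(tr.y, 0.0)

    def test_mean_frame_displacement_matches_velocity(self):
        tr = simulate_motility_trajectory(691.0, 1e5, 0.1, 0.0, seed=6)
        d = np.diff(tr.x)
        assert d.mean() == pytest.approx(69.1, rel=0.05)

    def test_ensemble_mean_run_length_converges(self):
        rng = np.random.default_rng(8)
        true_lengths = [
            simulate_motility_trajectory(100.0, 780.0, 0.1, 4.0, seed=rng)
            .meta["true_run_length"] for _ in range(300)]
        se = np.std(true_lengths, ddof=1) / np.sqrt(300)
        assert np.mean(true_lengths) == pytest.approx(780.0, abs=3 * se)

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            simulate_motility_trajectory(-1.0, 780.0, 0.1, 4.0)


class TestImageStack:
    def test_zero_photons_gives_pure_background(self):
        from myostep.localize import Trajectory

        tr = Trajectory([0], [0.0], [1000.0], [1000.0])
        stack = simulate_image_stack([tr], photons_per_frame=0.0, background=7.0,
                                     shape=(32, 32), seed=0, poisson=False)
        assert np.all(stack.frames == 7.0)

    def test_out_of_field_spot_dropped_with_warning(self):
        from myostep.localize import Trajectory

        tr = Trajectory([0], [0.0], [1e6], [1e6])
        with pytest.warns(UserWarning, match="outside the field"):
            stack = simulate_image_stack([tr], shape=(32, 32), seed=0, poisson=False)
        assert stack.ground_truth.empty

    def test_ground_truth_recorded(self):
        from myostep.localize import Trajectory

        tr = Trajectory([0, 1], [0.0, 0.1], [910.0, 950.0], [1001.0, 1001.0])
        stack = simulate_image_stack([tr], shape=(32, 32), seed=0, poisson=False)
        assert len(stack.ground_truth) == 2
        assert stack.ground_truth.iloc[0]["x_px"] == pytest.approx(10.0)


class TestTruncatedSampling:
    def test_support(self):
        x = sample_truncated_run_lengths(150.0, 400.0, 5000, seed=0)
        assert x.min() >= 0.0 and x.max() <= 400.0

    def test_mean_matches_expectation(self):
        x = sample_truncated_run_lengths(150.0, 400.0, 100_000, seed=1)
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert x.mean() == pytest.approx(
            expected_measured_runlength(150.0, 400.0), abs=3 * se)

    def test_wide_window_recovers_exponential_mean(self):
        x = sample_truncated_run_lengths(50.0, 50_000.0, 100_000, seed=2)
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert x.mean() == pytest.approx(50.0, abs=3.5 * se)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            sample_truncated_run_lengths(-1.0, 10.0, 5)
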