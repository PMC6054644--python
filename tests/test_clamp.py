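"""Force-clamp detector chain: events, steps, runs, per-force statistics."""

import numpy as np
import pytest

from myostep.clamp import (
    PositionRecord,
    Step,
    assemble_runs,
    bin_statistics,
    calibrate_threshold,
    detect_events,
    detect_steps_in_run,
    analyze_record,
    sliding_velocity,
    Run,
)
from myostep.simulate import ClampConfig, MotorModel, simulate_clamp_record

FS = 20_000.0


def record_from_position(pos, force=1.0, fs=FS, meta=None):
    return PositionRecord(pos, np.full(len(pos), float(force)), fs, meta=meta or {})


class TestEventDetection:
    def test_window_too_short_raises(self):
        rec = record_from_position(np.zeros(1000))
        with pytest.raises(ValueError, match="3 samples"):
            detect_events(rec, 100.0, window_s=1e-5)

    def test_all_stopped_record_single_interval(self):
        rec = record_from_position(np.zeros(5000))
        (i0, i1), = detect_events(rec, 4000.0, v_ref=10_000.0)
        assert i0 < 50 and i1 > 4950

    def test_noiseless_motor_free_has_no_events(self):
        cfg = ClampConfig(1.0, 400.0, sample_rate=FS, noise_sigma=0.0,
                          drag_velocity=8000.0, seed=0)
        rec = simulate_clamp_record(MotorModel(), cfg, duration=2.0, attach=False)
        assert detect_events(rec, 4000.0) == []

    def test_noiseless_attachments_recovered_with_tight_boundaries(self):
        cfg = ClampConfig(1.5, 400.0, sample_rate=FS, noise_sigma=0.0,
                          drag_velocity=10_000.0, seed=5)
        rec = simulate_clamp_record(MotorModel(attach_rate=2.0), cfg, duration=5.0)
        events = detect_events(rec, 5000.0)
        truth = [g for g in rec.ground_truth if g["t_detach"] - g["t_attach"] > 4e-3]
        assert len(events) == len(truth)
        # boundaries land within the velocity window, except when the
        # hysteresis merges an oscillation-apex dip just before an
        # attachment (at most ~2 windows early)
        for (i0, i1), g in zip(events, truth):
            assert i0 / FS == pytest.approx(g["t_attach"], abs=2.5e-3)
            assert i1 / FS == pytest.approx(g["t_detach"], abs=2.5e-3)


class TestCalibration:
    @staticmethod
    def motor_free(noise, seeds, duration=0.25):
        # the velocity-noise floor scales with the sampling rate, so
        # calibration runs at the acquisition rate of the instrument
        return [simulate_clamp_record(
            MotorModel(),
            ClampConfig(1.5, 400.0, sample_rate=200_000.0, noise_sigma=noise,
                        drag_velocity=10_000.0, seed=s),
            duration=duration, attach=False) for s in seeds]

    def test_zero_noise_any_threshold_is_admissible(self):
        recs = self.motor_free(0.0, range(5))
        thr = calibrate_threshold(recs, 0.01)
        assert thr > 0
        assert all(detect_events(r, thr) == [] for r in recs)

    def test_calibrated_threshold_holds_on_heldout_records(self):
        recs = self.motor_free(8.0, range(60))
        thr = calibrate_threshold(recs, 0.01)
        held = self.motor_free(8.0, range(500, 560))
        false_rate = np.mean([bool(detect_events(r, thr)) for r in held])
        assert false_rate <= 0.01

    def test_threshold_grows_with_noise(self):
        thr1 = calibrate_threshold(self.motor_free(4.0, range(30)), 0.01)
        thr2 = calibrate_threshold(self.motor_free(8.0, range(30)), 0.01)
        assert thr2 > thr1


def staircase(plateaus, dwell_s=0.02, fs=FS):
    return np.concatenate([np.full(int(dwell_s * fs), p) for p in plateaus])


class TestStepDetection:
    def test_noiseless_staircase_exact(self):
        pos = staircase([0.0, 36.0, 72.0, 108.0, 144.0])
        steps, means, _ = detect_steps_in_run(pos, FS)
        assert len(steps) == 4
        assert all(s.size == pytest.approx(36.0, abs=1e-9) for s in steps)
        assert means == pytest.approx([0, 36, 72, 108, 144], abs=1e-9)

    def test_backward_steps_detected_with_sign(self):
        pos = staircase([0.0, 36.0, 6.0])
        steps, _, _ = detect_steps_in_run(pos, FS)
        assert [round(s.size) for s in steps] == [36, -30]

    def test_unresolved_pair_merges_into_double_step(self):
        # two 36-nm steps separated by less than the velocity window
        pos = np.concatenate([np.full(400, 0.0), np.full(3, 36.0),
                              np.full(400, 72.0)])
        steps, _, _ = detect_steps_in_run(pos, FS)
        assert len(steps) == 1
        assert steps[0].size == pytest.approx(72.0, abs=1e-6)

    def test_short_segment_returns_no_steps(self):
        steps, _, _ = detect_steps_in_run(np.zeros(5), FS)
        assert steps == []


class TestRunAssembly:
    @staticmethod
    def steps_at(times, sizes):
        out, prev = [], 0.0
        for t, s in zip(times, sizes):
            out.append(Step(time=t, size=s, dwell_before=t - prev))
            prev = t
        return out

    def test_close_lattice_steps_form_one_run(self):
        steps = self.steps_at(np.arange(5) * 1e-3, [36.0] * 5)
        runs = assemble_runs(steps)
        assert len(runs) == 1
        assert runs[0].run_length == pytest.approx(180.0)

    def test_oversized_step_splits_run(self):
        steps = self.steps_at(np.arange(5) * 1e-3, [36.0, 36.0, 95.0, 36.0, 36.0])
        runs = assemble_runs(steps)
        assert len(runs) == 2

    def test_wide_gaps_isolate_each_step(self):
        steps = self.steps_at(np.arange(4) * 5e-3, [36.0] * 4)
        runs = assemble_runs(steps)
        assert len(runs) == 4

    def test_empty_input_empty_output(self):
        assert assemble_runs([]) == []


class TestChainOracle:
    def test_noiseless_chain_reproduces_ground_truth(self):
        from conftest import merge_truth_runs

        cfg = ClampConfig(1.5, 400.0, sample_rate=FS, noise_sigma=0.0,
                          drag_velocity=10_000.0, seed=5)
        rec = simulate_clamp_record(MotorModel(attach_rate=2.0), cfg, duration=5.0)
        runs = analyze_record(rec)
        truth = merge_truth_runs(rec.ground_truth)
        assert len(runs) == len(truth)
        for r, g in zip(runs, truth):
            assert r.force == pytest.approx(g["force"])
            assert r.run_length == pytest.approx(
                g["pos_detach"] - g["pos_attach"], abs=1e-6)
            # detected steps sum to the true displacement even when two
            # sub-resolution steps merge into one
            assert sum(s.size for s in r.steps) == pytest.approx(
                r.run_length, abs=1e-6)

    def test_run_length_equals_sum_of_steps_noiseless(self):
        pos = np.concatenate([staircase([0.0, 36.0, 72.0])])
        rec = record_from_position(pos, force=1.0)
        runs = analyze_record(rec, threshold=4000.0)
        # v_ref falls back to a percentile; force a sensible reference
        steps, means, _ = detect_steps_in_run(pos, FS)
        assert sum(s.size for s in steps) == pytest.approx(72.0, abs=1e-9)


class TestBinStatistics:
    @staticmethod
    def run(force, tau, length=100.0, steps=()):
        return Run(t_start=0.0, t_end=tau, pos_start=0.0, pos_end=length,
                   steps=list(steps), force=force)

    def test_single_run_detachment_rate(self):
        stats = bin_statistics([self.run(1.0, 0.5)], [0.5, 1.5])
        assert stats[0].detachment_rate == pytest.approx(2.0)
        assert stats[0].n_runs == 1

    def test_error_propagation_identity(self):
        taus = [0.2, 0.4, 0.8, 1.0]
        runs = [self.run(1.0, t) for t in taus]
        s = bin_statistics(runs, [0.5, 1.5])[0]
        sem_tau = np.std(taus, ddof=1) / 2.0
        assert s.detachment_rate_se == pytest.approx(
            sem_tau / np.mean(taus) ** 2)

    def test_equal_counts_give_unit_ratio(self):
        steps = [Step(0.1, 36.0, 0.1), Step(0.2, -30.0, 0.1)]
        s = bin_statistics([self.run(2.0, 1.0, steps=steps)], [1.5, 2.5])[0]
        assert s.ratio_fwd_bwd == pytest.approx(1.0)
        assert s.ratio_defined

    def test_no_backward_steps_flags_ratio(self):
        steps = [Step(0.1, 36.0, 0.1)]
        s = bin_statistics([self.run(2.0, 1.0, steps=steps)], [1.5, 2.5])[0]
        assert not s.ratio_defined and np.isnan(s.ratio_fwd_bwd)

    def test_binning_is_a_partition(self):
        forces = [-2.5, 0.3, 1.2, 2.2, 4.0]  # 4.0 out of range; [-1.5,0) empty
        runs = [self.run(f, 1.0) for f in forces]
        with pytest.warns(UserWarning, match="empty force bin"):
            stats = bin_statistics(runs, [-3.0, -1.5, 0.0, 1.5, 3.0])
        assert sum(s.n_runs for s in stats) == 4

    def test_stepping_rate_is_count_over_attached_time(self):
        steps = [Step(0.1, 36.0, 0.1), Step(0.3, 36.0, 0.2)]
        runs = [self.run(1.0, 2.0, steps=steps), self.run(1.0, 2.0)]
        s = bin_statistics(runs, [0.5, 1.5])[0]
        assert s.stepping_rate_fwd == pytest.approx(2 / 4.0)

    def test_detachment_rate_rises_with_resistive_force(self):
        from myostep.simulate import simulate_stepping

        rng = np.random.default_rng(12)
        model = MotorModel()
        runs = []
        for f in [0.7, 1.3, 1.9, 2.5]:
            for _ in range(150):
                tr = simulate_stepping(model, f, 50.0, seed=rng)
                runs.append(Run(0.0, tr.duration, 0.0, tr.run_length, [], f))
        stats = bin_statistics(runs, [0.4, 1.0, 1.6, 2.2, 2.8])
        k = [s.detachment_rate for s in stats]
        assert all(b > a for a, b in zip(k, k[1:]))


class TestRecordIO:
    def test_hdf5_round_trip(self, tmp_path):
        cfg = ClampConfig(1.0, 400.0, sample_rate=FS, seed=1)
        rec = simulate_clamp_record(MotorModel(), cfg, duration=0.5)
        path = tmp_path / "rec.h5"
        rec.to_hdf5(path)
        back = PositionRecord.from_hdf5(path)
        assert np.array_equal(back.position, rec.position)
        assert np.array_equal(back.force, rec.force)
        assert back.meta["force_magnitude"] == 1.0
        assert back.ground_truth == rec.ground_truth
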