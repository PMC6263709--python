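"""Synthetic study generator: posture geometry, burst model, calorimetry."""

import numpy as np
import pytest

from sedmet.calorimetry import compute_rmr, task_met
from sedmet.features import freq_features
from sedmet.io import CalorimeterTrace, EMG_CHANNELS
from sedmet.synth import (
    GeneratorConfig,
    ParticipantProfile,
    analog_frontend,
    default_task_models,
    generate_study,
    hard_preset,
    simulate_accel,
    simulate_calorimeter,
    simulate_emg_envelope,
    simulate_emg_raw,
)
from sedmet.tree import posture_tree

PROFILE = ParticipantProfile("P01", 1.4, (1.0,) * 8, 1.8)


class TestSimulateAccel:
    def test_standing_noiseless_is_constant_at_minus_one(self):
        cfg = GeneratorConfig(accel_noise=0.0, standing_sway=0.0)
        rec = simulate_accel("standing", 60.0, PROFILE, cfg, np.random.default_rng(0))
        assert np.all(rec.y == -1.0)
        p5, p95 = np.percentile(rec.y, [5, 95])
        assert p5 == p95 == -1.0

    def test_horizontal_sitting_noiseless_reads_zero_and_passes_sitting_rule(self):
        cfg = GeneratorConfig(
            accel_noise=0.0, sitting_angle_mean=90.0, sitting_angle_sd=0.0,
            sitting_angle_min=90.0, sitting_angle_max=90.0,
        )
        rec = simulate_accel("sitting", 60.0, PROFILE, cfg, np.random.default_rng(0))
        assert np.allclose(rec.y, 0.0, atol=1e-12)
        assert np.percentile(rec.y, 5) >= -0.774

    def test_default_sitting_always_above_sitting_threshold(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(11)
        for _ in range(100):
            rec = simulate_accel("sitting", 60.0, PROFILE, cfg, rng)
            assert np.percentile(rec.y, 5) >= -0.774

    def test_walking_excursions_leave_standing_band(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(3)
        rec = simulate_accel("walking", 60.0, PROFILE, cfg, rng)
        assert np.percentile(rec.y, 5) < -1.35
        assert np.percentile(rec.y, 95) > -0.85

    def test_quasi_static_magnitude_near_one_g(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(5)
        for posture in ("sitting", "standing", "lying"):
            rec = simulate_accel(posture, 60.0, PROFILE, cfg, rng)
            mag = np.linalg.norm(rec.data, axis=0)
            assert np.mean(mag) == pytest.approx(1.0, abs=0.05)

    def test_unknown_posture_rejected(self):
        with pytest.raises(ValueError, match="posture"):
            simulate_accel("flying", 60.0, PROFILE, GeneratorConfig(),
                           np.random.default_rng(0))


class TestEmgModel:
    def test_met_one_is_baseline_only(self):
        model = default_task_models()[("video", "sitting")]
        env = simulate_emg_envelope(model, 1.0, 60.0, PROFILE, GeneratorConfig(),
                                    np.random.default_rng(0))
        cfg = GeneratorConfig()
        # half-normal baseline: mean sigma*sqrt(2/pi), no burst power on top
        assert np.mean(env) == pytest.approx(cfg.emg_baseline * np.sqrt(2 / np.pi), rel=0.1)

    def test_envelope_amplitude_strictly_increasing_in_met(self):
        model = default_task_models()[("typing", "sitting")]
        cfg = GeneratorConfig()
        wins = 0
        for seed in range(50):
            lo = simulate_emg_envelope(model, 1.1, 60.0, PROFILE, cfg,
                                       np.random.default_rng(seed))
            hi = simulate_emg_envelope(model, 2.9, 60.0, PROFILE, cfg,
                                       np.random.default_rng(1000 + seed))
            dominant = [0, 4]  # forearm channels for typing
            if np.mean(hi[dominant]) > np.mean(lo[dominant]):
                wins += 1
        assert wins == 50

    def test_typing_forearm_bursts_exceed_lower_back(self):
        model = default_task_models()[("typing", "sitting")]
        cfg = GeneratorConfig()
        fore, back = [], []
        for seed in range(50):
            env = simulate_emg_envelope(model, 1.4, 60.0, PROFILE, cfg,
                                        np.random.default_rng(seed))
            fore.append(np.mean(env[[0, 4]]))
            back.append(np.mean(env[[3, 7]]))
        assert np.mean(fore) > np.mean(back)

    def test_envelope_nonnegative(self):
        model = default_task_models()[("deskwork", "standing")]
        env = simulate_emg_envelope(model, 2.0, 60.0, PROFILE, GeneratorConfig(),
                                    np.random.default_rng(7))
        assert np.min(env) >= 0.0

    def test_met_below_one_rejected(self):
        model = default_task_models()[("video", "sitting")]
        with pytest.raises(ValueError):
            simulate_emg_envelope(model, 0.9, 60.0, PROFILE, GeneratorConfig(),
                                  np.random.default_rng(0))


class TestAnalogFrontend:
    def test_dc_input_removed(self):
        out = analog_frontend(np.full((8, 4000), 5.0), raw_rate=1000.0)
        assert np.max(out.data) < 0.05

    def test_low_frequency_attenuated_vs_passband(self):
        t = np.arange(8000) / 1000.0
        below = analog_frontend(np.tile(np.sin(2 * np.pi * 1.0 * t), (8, 1)), 1000.0)
        inband = analog_frontend(np.tile(np.sin(2 * np.pi * 50.0 * t), (8, 1)), 1000.0)
        assert np.mean(inband.data) > 10 * np.mean(below.data)

    def test_output_nonnegative_any_input(self, rng):
        raw = rng.normal(size=(8, 4000))
        out = analog_frontend(raw, 1000.0)
        assert np.min(out.data) >= 0.0
        assert out.sample_rate == 30.0

    def test_rate_below_nyquist_of_cutoff_rejected(self):
        with pytest.raises(ValueError, match="220"):
            analog_frontend(np.zeros((1, 100)), raw_rate=200.0)

    def test_raw_path_envelope_recovers_burst_activity(self):
        model = default_task_models()[("typing", "sitting")]
        cfg = GeneratorConfig()
        raw_lo = simulate_emg_raw(model, 1.0, 8.0, PROFILE, cfg, np.random.default_rng(0))
        raw_hi = simulate_emg_raw(model, 2.9, 8.0, PROFILE, cfg, np.random.default_rng(0))
        env_lo = analog_frontend(raw_lo, cfg.raw_emg_rate)
        env_hi = analog_frontend(raw_hi, cfg.raw_emg_rate)
        assert np.mean(env_hi.data[0]) > np.mean(env_lo.data[0])


class TestSimulateCalorimeter:
    def _schedule(self):
        return [("typing", "sitting", 0.0, 300.0, 1.5),
                ("lying", "lying", 300.0, 900.0, 1.0)]

    def test_lying_zero_noise_settles_to_rmr(self):
        cfg = GeneratorConfig(calorimeter_noise_frac=0.0)
        trace = simulate_calorimeter(PROFILE, self._schedule(), cfg,
                                     np.random.default_rng(0))
        lying = CalorimeterTrace(trace.values[30:90], sample_rate=0.1)
        assert compute_rmr(lying).value == pytest.approx(PROFILE.rmr, rel=0.01)

    def test_task_zero_noise_is_met_times_rmr(self):
        cfg = GeneratorConfig(calorimeter_noise_frac=0.0)
        trace = simulate_calorimeter(PROFILE, self._schedule(), cfg,
                                     np.random.default_rng(0))
        assert np.allclose(trace.values[:30], 1.5 * PROFILE.rmr)

    def test_met_recovery_within_pm_0p05(self):
        # full pipeline recovery: rmr from lying, task met from final 2 min
        study = generate_study(GeneratorConfig(seed=21, n_participants=25))
        errors = []
        for s in study.sessions:
            lying = next(a for a in s.annotations if a.task == "lying")
            i0 = int(lying.start * 0.1)
            rmr = compute_rmr(
                CalorimeterTrace(s.calorimeter.values[i0:i0 + 60], 0.1)
            )
            for r in s.task_truth.itertuples(index=False):
                if r.task == "lying":
                    continue
                label = task_met(s.calorimeter, (r.start, r.end), rmr)
                errors.append(abs(label.met - r.met))
        assert np.mean(errors) < 0.02
        assert np.quantile(errors, 0.95) < 0.05


class TestGenerateStudy:
    def test_mandatory_tasks_present_for_everyone(self, small_study):
        for s in small_study.sessions:
            pairs = {(a.task, a.posture) for a in s.annotations}
            assert {("typing", "sitting"), ("typing", "standing"),
                    ("video", "sitting"), ("walking", "walking")} <= pairs
            assert ("lying", "lying") in pairs

    def test_mandatory_tasks_within_first_six_blocks(self, small_study):
        for s in small_study.sessions:
            order = [(a.task, a.posture) for a in s.annotations if a.task != "lying"]
            head = set(order[:6])
            assert {("typing", "sitting"), ("typing", "standing"),
                    ("video", "sitting"), ("walking", "walking")} <= head

    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(seed=13, n_participants=2)
        a, b = generate_study(cfg), generate_study(cfg)
        for sa, sb in zip(a.sessions, b.sessions):
            np.testing.assert_array_equal(sa.emg.data, sb.emg.data)
            np.testing.assert_array_equal(sa.accel.data, sb.accel.data)
            np.testing.assert_array_equal(sa.calorimeter.values, sb.calorimeter.values)
            assert sa.task_truth.equals(sb.task_truth)

    def test_sitting_sedentary_fraction_in_calibrated_band(self):
        study = generate_study(GeneratorConfig(seed=3, n_participants=25))
        truth = study.ground_truth_frame()
        sit = truth[truth["posture"] == "sitting"]
        frac = np.mean(sit["met_category"] == "inactive")
        assert 0.75 <= frac <= 0.95

    def test_default_preset_posture_is_perfectly_separable(self, small_minutes):
        clf = posture_tree()
        task_minutes = [m for m in small_minutes if m.posture != "lying"]
        acc = np.mean(
            [clf.classify_minute(m.accel_y) == m.posture for m in task_minutes]
        )
        assert acc == 1.0

    def test_hard_preset_defeats_the_fixed_tree(self):
        study = generate_study(hard_preset(GeneratorConfig(seed=2, n_participants=4)))
        clf = posture_tree()
        minutes = [m for m in study.labeled_minutes() if m.posture != "lying"]
        acc = np.mean([clf.classify_minute(m.accel_y) == m.posture for m in minutes])
        assert acc < 1.0

    def test_walking_met_always_active(self, small_study):
        truth = small_study.ground_truth_frame()
        walk = truth[truth["task"] == "walking"]
        assert (walk["met"] > 1.5).all()
        assert (walk["met_category"] == "active").all()

    def test_channel_count_and_nonnegativity(self, small_study):
        s = small_study.sessions[0]
        assert s.emg.data.shape[0] == len(EMG_CHANNELS)
        assert np.min(s.emg.data) >= 0.0
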