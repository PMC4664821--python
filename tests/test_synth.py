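"""Generator checks: analytic profile properties, round trips, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from rtg.errors import ParameterError
from rtg.synth import (
    EffectSizes,
    SynthConfig,
    TrialRecording,
    _aperture_at,
    draw_subject_effects,
    generate_aperture_profile,
    generate_dataset,
    generate_mep_sweep,
    generate_transport_profile,
    generate_trial,
    write_dataset,
)
from rtg.mep import peak_to_peak


class TestTransportProfile:
    def test_minimum_jerk_analytic_peak_speed(self):
        # peak speed of the minimum-jerk polynomial is 15 D / (8 T) at T/2
        x = generate_transport_profile(0.30, 1.0, 1000.0)
        v = np.gradient(x) * 1000.0
        assert v.max() == pytest.approx(15 * 0.30 / 8, abs=1e-5)
        assert np.argmax(v) == 500

    def test_discrete_peak_speed_at_120hz(self):
        x = generate_transport_profile(0.30, 1.0, 120.0)
        v = np.gradient(x) * 120.0
        assert v.max() == pytest.approx(0.5625, abs=1e-3)

    def test_boundary_conditions(self):
        x = generate_transport_profile(0.30, 1.0, 120.0)
        assert x[0] == 0.0
        assert x[-1] == pytest.approx(0.30, abs=1e-12)

    def test_zero_distance_gives_zero_series(self):
        assert np.all(generate_transport_profile(0.0, 1.0, 120.0) == 0.0)

    @pytest.mark.parametrize("bad", [(-0.1, 1, 120), (0.3, 0, 120), (0.3, 1, -5)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ParameterError):
            generate_transport_profile(*bad)


class TestApertureProfile:
    def test_peak_equals_diameter_plus_margin(self):
        a = generate_aperture_profile(0.072, 0.02, 1.0, 0.5, 120.0)
        assert a.max() == pytest.approx(0.092, abs=1e-12)

    def test_peak_time_on_grid(self):
        a = generate_aperture_profile(0.012, 0.03, 1.0, 0.7, 120.0)
        assert abs(np.argmax(a) - 84) <= 1  # 0.7 s at 120 Hz

    def test_object_size_shifts_peak_by_diameter_difference(self):
        small = generate_aperture_profile(0.012, 0.02, 1.0, 0.5, 120.0)
        large = generate_aperture_profile(0.072, 0.02, 1.0, 0.5, 120.0)
        assert large.max() - small.max() == pytest.approx(0.060, abs=1e-12)

    def test_endpoints(self):
        a = generate_aperture_profile(0.072, 0.02, 1.0, 0.5, 120.0, baseline=0.005)
        assert a[0] == pytest.approx(0.005, abs=1e-12)
        assert a[-1] == pytest.approx(0.072, abs=1e-12)

    @pytest.mark.parametrize("diameter,margin,m", [
        (0.012, 0.03, 0.5), (0.072, 0.03, 0.5), (0.012, 0.01, 0.7), (0.072, 0.05, 0.3),
    ])
    def test_unimodal(self, diameter, margin, m):
        a = generate_aperture_profile(diameter, margin, 1.2, m, 120.0)
        d = np.diff(a)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-15])) != 0)
        assert sign_changes <= 1

    def test_negative_margin_rejected(self):
        with pytest.raises(ParameterError):
            generate_aperture_profile(0.072, -0.01, 1.0, 0.5, 120.0)

    @pytest.mark.parametrize("m", [0.0, 1.0, -0.2])
    def test_peak_fraction_bounds(self, m):
        with pytest.raises(ParameterError):
            generate_aperture_profile(0.072, 0.02, 1.0, m, 120.0)


class TestTrialGeneration:
    def test_missing_rng_rejected(self, zero_noise_config, subject):
        with pytest.raises(ParameterError, match="Generator"):
            generate_trial(zero_noise_config, subject, "sham", "pre", "small", None)

    def test_zero_noise_aperture_round_trip(self, zero_noise_config, subject, rng):
        rec = generate_trial(zero_noise_config, subject, "sham", "pre", "large", rng)
        aperture = np.linalg.norm(rec.thumb_xyz - rec.index_xyz, axis=1)
        tau = (rec.timestamps - rec.hand_lift - rec.truth.shift) / rec.truth.tmt
        expected = _aperture_at(
            tau, zero_noise_config.object_diameters["large"],
            rec.truth.a_max - zero_noise_config.object_diameters["large"],
            zero_noise_config.aperture_peak_fraction,
            zero_noise_config.aperture_baseline,
        )
        assert np.max(np.abs(aperture - expected)) < 1e-12

    def test_event_order_and_sampling(self, default_config, subject, rng):
        rec = generate_trial(default_config, subject, "real", "post", "small", rng)
        assert rec.led_onset <= rec.hand_lift < rec.object_lift <= rec.timestamps[-1]
        assert np.allclose(np.diff(rec.timestamps), 1 / 120.0, atol=1e-12)

    def test_recording_invariant_validation(self):
        t = np.arange(10) / 120.0
        pos = np.zeros((10, 3))
        with pytest.raises(ParameterError, match="event order"):
            TrialRecording(
                "S1", "sham", "pre", "small", 0, t, pos, pos, pos,
                led_onset=0.05, hand_lift=0.04, object_lift=0.03, fs=120.0,
            )

    def test_config_invariants(self):
        with pytest.raises(ParameterError):
            SynthConfig(object_diameters={"small": 0.08, "large": 0.072})
        with pytest.raises(ParameterError):
            SynthConfig(reach_distance=-1.0)
        with pytest.raises(ParameterError):
            EffectSizes(mep_suppression_fraction=1.0)

    def test_dataset_determinism_byte_identical(self, tmp_path):
        cfg = replace(SynthConfig(), n_subjects=2, trials_per_block=1, seed=7)
        for d in ("a", "b"):
            trials = generate_dataset(cfg)
            write_dataset(trials, tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


class TestMEPSweeps:
    def test_peak_to_peak_exact_at_zero_noise(self, rng):
        sweep = generate_mep_sweep(800.0, 0.0, 2000.0, rng)
        assert peak_to_peak(sweep).amplitude_uv == pytest.approx(800.0, abs=1e-9)

    def test_suppression_scales_amplitude(self, rng):
        sweep = generate_mep_sweep(800.0, 0.5, 2000.0, rng)
        assert peak_to_peak(sweep).amplitude_uv == pytest.approx(400.0, abs=1e-9)

    @pytest.mark.parametrize("supp", [-0.1, 1.0, 1.5])
    def test_suppression_bounds(self, supp, rng):
        with pytest.raises(ParameterError):
            generate_mep_sweep(800.0, supp, 2000.0, rng)

    def test_noisy_sweeps_unbiased(self, rng):
        # 10 sweeps at CV 10%: the mean stays within 3 SE of the target
        amps = [
            peak_to_peak(generate_mep_sweep(800.0, 0.0, 2000.0, rng, noise_cv=0.10)).amplitude_uv
            for _ in range(10)
        ]
        se = 800.0 * 0.10 / np.sqrt(10)
        assert abs(np.mean(amps) - 800.0) < 3 * se


def test_subject_effects_require_rng(default_config):
    with pytest.raises(ParameterError):
        draw_subject_effects(default_config, None)
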