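"""Distance estimation, range gating, micro-motion signature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uwbradar as u
from uwbradar.micromotion import (
    SEGMENT_RANGE_M,
    NoMovementError,
    SignatureSpec,
)
from uwbradar.simulate import fall_scene


class TestRangeCumsum:
    def test_zeros_in_zeros_out(self):
        assert not u.range_cumsum(np.zeros((16, 32))).any()

    def test_step_at_concentrated_energy(self):
        frame = np.zeros((16, 32))
        frame[:, 10] = 2.0
        cs = u.range_cumsum(frame)
        assert cs[9] == 0.0
        assert cs[10] == pytest.approx(16 * 4.0)
        assert cs[-1] == pytest.approx(cs[10])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_with_total_energy_last(self, seed):
        frame = np.random.default_rng(seed).random((8, 24))
        cs = u.range_cumsum(frame)
        assert np.all(np.diff(cs) >= 0)
        assert cs[-1] == pytest.approx((frame**2).sum())


class TestEstimateDistance:
    def test_ideal_step_returns_step_range(self):
        axis = np.linspace(0.5, 5.5, 200)
        cs = np.where(axis >= 3.0, 1.0, 0.0).cumsum()
        d = u.estimate_distance(cs, axis)
        assert d == pytest.approx(3.0, abs=0.1)

    def test_linear_ramp_degenerate_tie_breaks_near(self):
        axis = np.linspace(0.5, 5.5, 100)
        cs = np.linspace(0.0, 1.0, 100)
        d = u.estimate_distance(cs, axis)
        assert d <= axis[2]  # smallest-range tie

    def test_constant_cumsum_means_no_subject(self):
        axis = np.linspace(0.5, 5.5, 50)
        assert np.isnan(u.estimate_distance(np.zeros(50), axis))

    def test_invariant_to_positive_rescaling(self, rng):
        axis = np.linspace(0.5, 5.5, 80)
        cs = np.cumsum(rng.random(80))
        assert u.estimate_distance(cs, axis) == u.estimate_distance(37.5 * cs, axis)

    def test_walker_distance_recovery(self, full_plan):
        errs = []
        for seed in range(6):
            scene = u.SceneScript(
                actors=(
                    u.Actor(kind="walker", base_range=2.5, walk_span=0.6, walk_speed=0.4),
                ),
                duration=15.0,
                seed=seed,
            )
            scan, truth = u.render_scans(scene, full_plan)
            cf = u.svd_clutter_removal(u.apply_fasttime_filter(scan))
            sigs = u.extract_signature(u.doppler_spectrogram(cf))
            t = truth["time_s"].to_numpy()
            r = truth["range_m"].to_numpy()
            errs += [
                abs(s.distance - np.interp(s.window_start + 0.8, t, r))
                for s in sigs
                if np.isfinite(s.distance)
            ]
        assert np.median(errs) <= 0.5


class TestGainFunction:
    def test_unity_maximum_at_origin(self):
        assert u.gain_function(0.0) == pytest.approx(1.0)
        x = np.linspace(-6, 6, 1001)
        assert u.gain_function(x).max() == pytest.approx(1.0, abs=1e-6)

    def test_asymptotes(self):
        assert u.gain_function(-30.0) == pytest.approx(0.0, abs=1e-9)
        assert u.gain_function(30.0) == pytest.approx(8.0 / 9.0, abs=1e-9)

    def test_apply_range_gain_scales_columns(self):
        axis = np.linspace(0.5, 5.5, 100)
        frame = np.ones((16, 100))
        gated = u.apply_range_gain(frame, 3.0, axis)
        j_at = np.argmin(np.abs(axis - 3.0))
        j_before = np.argmin(np.abs(axis - 1.0))
        j_after = np.argmin(np.abs(axis - 5.0))
        assert gated[:, j_at] == pytest.approx(1.0, abs=0.01)
        # h(-2) = 4(1+tanh(-2))/(2+tanh(-2))^2
        assert gated[0, j_before] == pytest.approx(0.1353, abs=0.002)
        assert gated[0, j_after] == pytest.approx(8.0 / 9.0, abs=0.01)
        # identical across Doppler rows
        assert np.allclose(gated, gated[0])


class TestSignatures:
    def test_window_duration_formula(self):
        spec = SignatureSpec(n_s=9)
        assert spec.window_duration(0.32) == pytest.approx(1.6)

    def test_static_breathing_profile_concentrated_at_low_doppler(
        self, clutter_free_scan
    ):
        sigs = u.extract_signature(u.doppler_spectrogram(clutter_free_scan))
        assert sigs
        profile = np.mean([s.profile for s in sigs], axis=0)
        sgram_freqs = np.fft.fftshift(np.fft.fftfreq(16, 1 / 50.0))
        low = np.abs(sgram_freqs) <= 6.25
        assert profile[low].sum() / profile.sum() > 0.9
        amps = np.array([s.amplitude for s in sigs])
        # resting subject: amplitude stays near its median (no event spikes)
        assert np.percentile(amps, 95) < 5 * np.median(amps)

    def test_single_frame_window_is_gated_frame_profile(self, clutter_free_scan):
        sgram = u.doppler_spectrogram(clutter_free_scan)
        sigs = u.extract_signature(sgram, SignatureSpec(n_s=1))
        energy = sgram.magnitude[0] ** 2
        cs = np.cumsum(energy.sum(axis=0))
        d = u.estimate_distance(cs, sgram.range_axis)
        gains = u.gain_function(sgram.range_axis - d)
        expected = (energy * gains[None, :]).sum(axis=1)
        assert np.allclose(sigs[0].profile, expected)
        central = int(np.argmin(np.abs(sgram.frequencies)))
        assert sigs[0].amplitude == pytest.approx(expected.sum() - expected[central])

    def test_fall_amplitude_peak_over_walking_baseline(self, short_plan):
        scene = fall_scene(11)
        faller = scene.actors[0]
        scan, _ = u.render_scans(scene, short_plan)
        cf = u.svd_clutter_removal(u.apply_fasttime_filter(scan))
        sigs = u.extract_signature(u.doppler_spectrogram(cf))
        t = np.array([s.window_start for s in sigs])
        amps = np.array([s.amplitude for s in sigs])
        walking = amps[(t > 1.0) & (t < faller.fall_time - 2.0)]
        fall = amps[(t >= faller.fall_time - 1.0) & (t <= faller.fall_time + 1.5)]
        post = amps[t > faller.fall_time + 5.0]
        assert fall.max() >= 5 * np.median(walking)
        assert np.median(post) < 0.05 * fall.max()


class TestMovementRegion:
    def test_centred_on_latest_distance_with_segment_width(self):
        sig = u.MicroMotionSignature(
            profile=np.ones(16), amplitude=16.0, distance=3.0, window_start=0.0
        )
        region = u.movement_region([sig])
        assert region.d1 == pytest.approx(3.0 - SEGMENT_RANGE_M / 2)
        assert region.d2 == pytest.approx(3.0 + SEGMENT_RANGE_M / 2)
        assert region.d2 - region.d1 == pytest.approx(0.878, abs=0.01)

    def test_no_movement_raises(self):
        sig = u.MicroMotionSignature(
            profile=np.zeros(16), amplitude=0.0, distance=np.nan, window_start=0.0
        )
        with pytest.raises(NoMovementError):
            u.movement_region([sig], movement_threshold=0.0)

    def test_latest_region_persists_through_still_windows(self):
        moving = u.MicroMotionSignature(
            profile=np.ones(16), amplitude=16.0, distance=2.0, window_start=0.0
        )
        still = u.MicroMotionSignature(
            profile=np.zeros(16), amplitude=0.0, distance=np.nan, window_start=1.0
        )
        region = u.movement_region([moving, still, still], movement_threshold=1.0)
        assert (region.d1 + region.d2) / 2 == pytest.approx(2.0)
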