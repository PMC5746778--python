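"""Slow-time filter, EMD sifting, mode weighting/selection, rate estimation."""

import numpy as np
import pytest
from scipy import signal

import uwbradar as u
from uwbradar import vitals as V


def slowtime_response_db(freq_hz: float) -> float:
    sos = V.slowtime_sos(V.design_slowtime_bandpass(), fs=50.0)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=50.0)
    return 2 * 20 * np.log10(np.abs(h[0]) + 1e-300)  # zero-phase application


class TestSlowtimeBandpass:
    def test_band_edges_match_physiological_limits(self):
        spec = V.design_slowtime_bandpass()
        assert spec.order == 6
        assert spec.passband_hz[0] * 60 == pytest.approx(7.5)  # breaths/min
        assert spec.passband_hz[1] * 60 == pytest.approx(180)  # beats/min

    def test_stopband_rejection_below_band(self):
        assert slowtime_response_db(0.05) <= -30.0

    def test_passband_keeps_vital_frequencies(self):
        for f in (0.25, 1.2):
            assert slowtime_response_db(f) >= -3.0


class TestSift:
    def test_pure_sine_one_dominant_mode(self):
        t = np.arange(3000) / 50.0
        s = np.sin(2 * np.pi * 0.25 * t)
        dec = V.sift(s)
        energies = [np.sum(m**2) for m in dec.modes]
        assert max(energies) / sum(energies) >= 0.99
        f = V.mean_frequency(dec.modes[int(np.argmax(energies))], 50.0)
        assert f == pytest.approx(0.25, abs=0.02)

    def test_separable_cardiorespiratory_mixture(self):
        # respiration sine + harmonic-rich cardiac impulse (the simulator's
        # waveform); the impulse dominates the derivative so sifting can
        # isolate it as the first mode
        actor = u.Actor(rr=15.0, hr=72.0)
        t = np.arange(3000) / 50.0
        resp = 0.1 * actor.resp_amplitude * np.sin(2 * np.pi * 0.25 * t)
        s = resp + u.simulate.cardiac_impulse(t, actor)
        dec = V.sift(s)
        f0 = V.mean_frequency(dec.modes[0], 50.0)
        assert f0 == pytest.approx(1.2, abs=0.12)

    def test_reconstruction_identity(self, rng):
        s = rng.normal(size=1500).cumsum()  # drifting, multi-scale
        dec = V.sift(s)
        err = np.linalg.norm(dec.reconstruct() - s) / np.linalg.norm(s)
        assert err < 1e-9

    def test_modes_satisfy_imf_conditions(self, rng):
        t = np.arange(2000) / 50.0
        s = (
            np.sin(2 * np.pi * 0.3 * t)
            + 0.4 * np.sin(2 * np.pi * 1.7 * t)
            + 0.05 * rng.normal(size=t.size)
        )
        dec = V.sift(s)
        assert dec.modes
        for mode in dec.modes:
            maxima, minima = V._local_extrema(mode)
            n_extrema = maxima.size + minima.size
            n_zc = V._count_zero_crossings(mode)
            assert abs(n_extrema - n_zc) <= 1

    def test_too_few_extrema_returns_residue_only(self):
        dec = V.sift(np.linspace(0.0, 1.0, 64))
        assert dec.n_modes == 0
        assert np.allclose(dec.residue, np.linspace(0.0, 1.0, 64))

    def test_short_series_rejected(self):
        with pytest.raises(V.VitalsError):
            V.sift(np.ones(5))


class TestImfWeight:
    def test_identical_series_zero_weight(self, rng):
        s = rng.normal(size=500)
        assert V.imf_weight(s, s, bin_width=s.std() / 4) == 0.0

    def test_unrelated_noise_weighs_more_than_near_copy(self, rng):
        t = np.arange(1000) / 50.0
        s = np.sin(2 * np.pi * 0.3 * t)
        near = s + 1e-3 * rng.normal(size=t.size)
        noise = rng.normal(size=t.size)
        bw = s.std() / 4
        assert V.imf_weight(s, noise, bw) > V.imf_weight(s, near, bw)

    def test_invariant_to_joint_translation(self, rng):
        t = np.arange(800) / 50.0
        s = np.sin(2 * np.pi * 0.4 * t)
        f = 0.3 * np.sin(2 * np.pi * 1.1 * t)
        bw = s.std() / 4
        assert V.imf_weight(s + 5.0, f + 5.0, bw) == pytest.approx(
            V.imf_weight(s, f, bw), rel=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        s = np.sin(np.arange(100.0))
        with pytest.raises(V.VitalsError):
            V.imf_weight(s, np.zeros(100), 0.1)
        with pytest.raises(V.VitalsError):
            V.imf_weight(s, s, 0.0)


class TestSelection:
    def test_min_after_last_noisy_maximum(self):
        assert V.select_imfs(np.array([0.3, 0.6, 0.4, 0.15, 0.2])) == 3

    def test_degenerate_two_modes(self):
        assert V.select_imfs(np.array([0.5, 0.2])) == 1

    def test_monotone_decreasing_selects_global_minimum(self):
        assert V.select_imfs(np.array([0.9, 0.7, 0.5, 0.3])) == 3

    def test_invariant_to_positive_rescaling(self):
        w = np.array([0.3, 0.6, 0.4, 0.15, 0.2])
        assert V.select_imfs(w) == V.select_imfs(123.0 * w)
        assert V.selected_mode_run(w) == V.selected_mode_run(123.0 * w)

    def test_run_covers_descending_segment(self):
        assert V.selected_mode_run(np.array([0.3, 0.6, 0.4, 0.15, 0.2])) == [2, 3]
        assert V.selected_mode_run(np.array([0.5, 0.2])) == [1]


class TestMeanFrequency:
    def test_sine_zero_crossing_rate(self):
        t = np.arange(3000) / 50.0
        assert V.mean_frequency(np.sin(2 * np.pi * 1.2 * t), 50.0) == pytest.approx(
            1.2, abs=0.02
        )

    def test_hilbert_method_agrees_on_clean_tone(self):
        t = np.arange(3000) / 50.0
        s = np.sin(2 * np.pi * 0.8 * t)
        assert V.mean_frequency(s, 50.0, method="hilbert") == pytest.approx(0.8, abs=0.05)


class TestEstimateRates:
    def test_resting_subject_recovery(self, clutter_free_scan):
        sigs = u.extract_signature(u.doppler_spectrogram(clutter_free_scan))
        region = u.movement_region(sigs)
        filtered = V.apply_slowtime_filter(clutter_free_scan)
        est = u.estimate_rates(filtered, region)
        assert est.rr == pytest.approx(15.0, abs=1.5)
        assert est.hr == pytest.approx(72.0, abs=4.0)

    def test_respiration_only_subject_flags_hr_missing(self, short_plan):
        scene = u.SceneScript(
            actors=(
                u.Actor(
                    kind="stationary_subject",
                    base_range=2.0,
                    resp_amplitude=0.002,  # gentle breathing: carrier
                    heart_amplitude=1e-9,  # harmonics stay out of the HR band
                ),
            ),
            duration=60.0,
            noise_sigma=0.0,
            seed=0,
        )
        scan, _ = u.render_scans(scene, short_plan)
        cf = u.svd_clutter_removal(
            u.apply_fasttime_filter(scan), u.ClutterRemovalSpec(n_components=1)
        )
        filtered = V.apply_slowtime_filter(cf)
        region = u.MovementRegion(1.6, 2.4)
        est = u.estimate_rates(filtered, region)
        assert est.flags["hr_missing"]
        assert est.rr == pytest.approx(15.0, abs=0.5)

    def test_rates_invariant_to_amplitude_scaling(self, clutter_free_scan):
        sigs = u.extract_signature(u.doppler_spectrogram(clutter_free_scan))
        region = u.movement_region(sigs)
        filtered = V.apply_slowtime_filter(clutter_free_scan)
        est1 = u.estimate_rates(filtered, region)
        est2 = u.estimate_rates(filtered.with_samples(17.0 * filtered.samples), region)
        assert est1.hr == pytest.approx(est2.hr, abs=1e-9)
        assert est1.rr == pytest.approx(est2.rr, abs=1e-9)

    def test_movement_flag_set_for_high_amplitude(self, clutter_free_scan):
        sigs = u.extract_signature(u.doppler_spectrogram(clutter_free_scan))
        region = u.movement_region(sigs)
        filtered = V.apply_slowtime_filter(clutter_free_scan)
        est = u.estimate_rates(
            filtered, region, movement_amplitude=10.0, movement_flag_threshold=1.0
        )
        assert est.flags["movement"]

    def test_short_window_rejected(self, clutter_free_scan):
        filtered = V.apply_slowtime_filter(clutter_free_scan)
        with pytest.raises(V.VitalsError):
            u.estimate_rates(filtered, u.MovementRegion(1.6, 2.4), window=(0.0, 5.0))
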