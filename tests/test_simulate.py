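"""Scene renderer: geometry, physiology, reproducibility, superposition."""

import numpy as np
import pytest

import uwbradar as u
from uwbradar.simulate import PULSE, SceneError, adl_scene, cardiac_impulse, fall_scene


def render(actors, plan, seed=0, noise=0.0, duration=10.0, interference=None):
    scene = u.SceneScript(
        actors=tuple(actors), duration=duration, noise_sigma=noise,
        interference=interference, seed=seed,
    )
    return u.render_scans(scene, plan)


class TestPulse:
    def test_spectral_peak_at_carrier(self):
        dt = PULSE.fast_time_step_ps / 1000.0  # ns
        t = np.arange(-512, 512) * dt
        p = PULSE(t)
        spectrum = np.abs(np.fft.rfft(p, n=16 * t.size))
        freqs = np.fft.rfftfreq(16 * t.size, dt)  # GHz
        peak = freqs[np.argmax(spectrum)]
        assert abs(peak - 4.3) < freqs[1] * 2

    def test_band_edges_at_minus_10db(self):
        t = np.linspace(-2, 2, 4001)
        p = np.exp(-(t**2) / (2 * PULSE.sigma_ns**2))
        spectrum = np.abs(np.fft.rfft(p))
        freqs = np.fft.rfftfreq(t.size, t[1] - t[0])
        # envelope spectrum at the half-bandwidth offset is -10 dB
        mag = np.interp(1.1, freqs, spectrum) / spectrum[0]
        assert 20 * np.log10(mag) == pytest.approx(-10.0, abs=0.3)


class TestChestDisplacement:
    def test_zero_at_origin(self):
        actor = u.Actor()
        assert u.chest_displacement(0.0, actor) == 0.0

    def test_amplitude_bound(self):
        actor = u.Actor()
        t = np.linspace(0, 60, 6000)
        d = u.chest_displacement(t, actor)
        assert np.max(np.abs(d)) <= actor.resp_amplitude + actor.heart_amplitude

    def test_spectral_lines_at_vital_frequencies(self):
        actor = u.Actor(rr=15.0, hr=72.0)
        t = np.arange(3000) / 50.0
        d = u.chest_displacement(t, actor)
        spectrum = np.abs(np.fft.rfft(d))
        freqs = np.fft.rfftfreq(3000, 0.02)
        top2 = freqs[np.argsort(spectrum)[-2:]]
        assert sorted(np.round(top2, 2).tolist()) == [0.25, 1.2]

    def test_clutter_has_no_vitals(self):
        with pytest.raises(SceneError):
            u.chest_displacement(0.0, u.Actor(kind="static_clutter"))

    def test_cardiac_impulse_peak_and_rate(self):
        actor = u.Actor(hr=72.0)
        t = np.arange(3000) / 50.0
        c = cardiac_impulse(t, actor)
        assert np.max(np.abs(c)) == pytest.approx(actor.heart_amplitude, rel=1e-3)
        spectrum = np.abs(np.fft.rfft(c))
        freqs = np.fft.rfftfreq(3000, 0.02)
        assert freqs[np.argmax(spectrum)] == pytest.approx(1.2, abs=0.02)


class TestRenderScans:
    def test_empty_scene_zero_noise_is_zeros(self, short_plan):
        scan, truth = render([], short_plan)
        assert not scan.samples.any()
        assert truth["people_count"].eq(0).all()

    def test_static_reflector_peak_bin(self, short_plan):
        target = 2.0
        scan, _ = render(
            [u.Actor(kind="static_clutter", base_range=target)], short_plan
        )
        peak_bin = int(np.argmax(np.abs(scan.samples[0])))
        expected = int(
            round(
                (2 * target / short_plan.constants.c + 10 - short_plan.t1)
                / short_plan.sample_step_ns
            )
        )
        assert abs(peak_bin - expected) <= 1
        # constant across slow time
        assert np.allclose(scan.samples[0], scan.samples[-1])

    def test_breathing_dominant_slow_time_frequency(self, short_plan):
        scan, _ = render(
            [u.Actor(kind="stationary_subject", base_range=2.0, rr=15.0)],
            short_plan, duration=60.0,
        )
        # remove the static component, inspect the strongest bin
        x = scan.samples - scan.samples.mean(axis=0)
        j = int(np.argmax(x.std(axis=0)))
        spectrum = np.abs(np.fft.rfft(x[:, j]))
        freqs = np.fft.rfftfreq(x.shape[0], 1 / short_plan.fs)
        assert freqs[np.argmax(spectrum)] == pytest.approx(0.25, abs=0.05)

    def test_bit_reproducibility(self, short_plan):
        scene = adl_scene(3, minute=1, duration=5.0)
        a, ta = u.render_scans(scene, short_plan)
        b, tb = u.render_scans(scene, short_plan)
        assert np.array_equal(a.samples, b.samples)
        assert ta.equals(tb)

    def test_superposition_of_actors(self, short_plan):
        actor_a = u.Actor(kind="stationary_subject", base_range=1.5)
        actor_b = u.Actor(kind="static_clutter", base_range=2.5, reflectivity=5.0)
        both, _ = render([actor_a, actor_b], short_plan)
        only_a, _ = render([actor_a], short_plan)
        only_b, _ = render([actor_b], short_plan)
        assert np.allclose(both.samples, only_a.samples + only_b.samples, atol=1e-12)

    def test_actor_outside_window_rejected(self, short_plan):
        with pytest.raises(SceneError):
            render([u.Actor(kind="static_clutter", base_range=5.0)], short_plan)

    def test_ground_truth_tracks_nearest_subject(self, short_plan):
        near = u.Actor(kind="stationary_subject", base_range=1.2, hr=80, rr=18)
        far = u.Actor(kind="stationary_subject", base_range=2.4, hr=60, rr=12)
        _, truth = render([near, far], short_plan)
        assert truth["people_count"].eq(2).all()
        assert truth["hr_bpm"].eq(80).all()
        assert np.allclose(truth["range_m"], 1.2, atol=0.01)

    def test_fall_kinematics(self, short_plan):
        scene = fall_scene(7)
        faller = scene.actors[0]
        assert faller.fall_peak_speed >= 2.0
        _, truth = u.render_scans(scene, short_plan)
        labels = truth["activity"].to_numpy()
        assert (labels == "walking").any()
        assert (labels == "fall").any()
        post = labels == "post-fall"
        assert post.sum() >= 10 * short_plan.fs  # sustained immobility
        # post-fall range is constant (subject immobile, vitals only)
        post_rng = truth.loc[post, "range_m"].to_numpy()
        assert np.ptp(post_rng) < 1e-9


class TestInterference:
    def test_zero_amplitude_is_identity(self, short_plan):
        scan, _ = render([u.Actor(kind="static_clutter", base_range=2.0)], short_plan)
        out = u.add_narrowband_interference(scan, 1.0, 0.0)
        assert np.array_equal(out.samples, scan.samples)

    def test_invertible_by_subtraction(self, short_plan):
        scan, _ = render([u.Actor(kind="static_clutter", base_range=2.0)], short_plan)
        noisy = u.add_narrowband_interference(scan, 1.0, 0.5, seed=9)
        zero = scan.with_samples(np.zeros_like(scan.samples))
        tone = u.add_narrowband_interference(zero, 1.0, 0.5, seed=9)
        assert np.allclose(noisy.samples - tone.samples, scan.samples)

    @pytest.mark.parametrize(
        "freq,min_rejection_db", [(1.0, 30.0)]
    )
    def test_out_of_band_tone_rejected_by_fasttime_filter(
        self, short_plan, freq, min_rejection_db
    ):
        zero = u.ScanMatrix(np.zeros((64, short_plan.n_bins)), short_plan)
        tone = u.add_narrowband_interference(zero, freq, 1.0, seed=1)
        filtered = u.apply_fasttime_filter(tone)
        rejection = 20 * np.log10(
            np.abs(tone.samples).max() / (np.abs(filtered.samples).max() + 1e-30)
        )
        assert rejection >= min_rejection_db

    def test_in_band_tone_substantially_preserved(self, short_plan):
        zero = u.ScanMatrix(np.zeros((64, short_plan.n_bins)), short_plan)
        tone = u.add_narrowband_interference(zero, 4.3, 1.0, seed=1)
        filtered = u.apply_fasttime_filter(tone)
        # interior bins: zero-phase passband loss is at most ~1 dB at centre
        mid = slice(32, -32)
        loss = 20 * np.log10(
            np.abs(tone.samples[:, mid]).max()
            / np.abs(filtered.samples[:, mid]).max()
        )
        assert loss <= 3.0
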