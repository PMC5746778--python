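"""Synthetic UWB impulse-radar scene renderer.

Generates slow-time x fast-time scan matrices with exact ground truth for
scripted indoor scenes: breathing/beating subjects at rest, walkers, falls,
static clutter, wideband noise and narrowband interference.  The emulated
front end is a monostatic impulse radar emitting a Gaussian-modulated cosine
pulse centred at 4.3 GHz with a 3.1-5.3 GHz (-10 dB) band, sampled in fast
time every 61.035 ps, with scans repeated at the slow-time rate of the
:class:`~uwbradar.mrm_timing.TimingPlan` (50 Hz by default).

Physiological motion rides on the kinematic path of the torso, which is
rendered as two point scatterers reflecting how a real trunk moves.  The
abdominal scatterer carries the full sinusoidal chest displacement:
respiration at 12 mm and the heartbeat at 0.6 mm peak-to-peak, the ~20x ratio
that makes cardiac extraction the hard part of radar vital-sign sensing.
The precordial scatterer, offset ~12 cm in range, moves with a tenth of
the respiratory excursion plus a pulsatile cardiac impulse (a
harmonic-rich waveform, as the apex beat is, rather than a pure tone): a
purely sinusoidal sub-millimetre heartbeat co-located with a centimetre
breathing motion would be unrecoverable by any envelope-based decomposition,
whereas the localized, pulsatile precordial motion is what radar systems
actually latch onto.  A walker is a constant-speed torso shuttling across a
corridor of range plus two counter-phase limb scatterers producing
micro-Doppler sidebands.  A fall is a rapid (~1 s) radial transition with
peak speed above 2 m/s and a radar-cross-section rise (the body ends prone
and broadside to the antenna), followed by immobility during which only the
vitals modulate the return.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GROUND_TRUTH_COLUMNS, ScanMatrix
from .mrm_timing import TimingPlan, snr_gain_db

__all__ = [
    "PulseModel",
    "Actor",
    "Interference",
    "SceneScript",
    "SceneError",
    "chest_displacement",
    "cardiac_impulse",
    "render_scans",
    "add_narrowband_interference",
    "adl_scene",
    "fall_scene",
    "ADL_BLOCK_MINUTES",
]


class SceneError(ValueError):
    """Scene configuration inconsistent with the timing plan."""


@dataclass(frozen=True)
class PulseModel:
    """Gaussian-modulated cosine radar pulse.

    ``sigma_ns`` is chosen so the -10 dB points of the power spectrum sit at
    the band edges, i.e. 1.1 GHz either side of the 4.3 GHz carrier:
    exp(-(2 pi df sigma)^2) = 0.1 at df = half-bandwidth.
    """

    center_frequency_ghz: float = 4.3
    band_ghz: tuple[float, float] = (3.1, 5.3)
    fast_time_step_ps: float = 32 * 1e6 / 2**19  # 61.035

    @property
    def sigma_ns(self) -> float:
        half_bw = (self.band_ghz[1] - self.band_ghz[0]) / 2.0
        return math.sqrt(math.log(10.0)) / (2.0 * math.pi * half_bw)

    def __call__(self, t_ns: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ns, dtype=np.float64)
        env = np.exp(-(t**2) / (2.0 * self.sigma_ns**2))
        return env * np.cos(2.0 * np.pi * self.center_frequency_ghz * t)


PULSE = PulseModel()

LIVING_KINDS = ("stationary_subject", "walker", "faller")


@dataclass(frozen=True)
class Actor:
    """One scene element: a person (with vitals and kinematics) or clutter.

    Defaults describe a resting adult: 15 breaths/min with 12 mm chest
    excursion, 72 beats/min with 0.6 mm excursion.
    """

    kind: str = "stationary_subject"
    base_range: float = 2.0
    rr: float = 15.0
    hr: float = 72.0
    resp_amplitude: float = 0.006  # sine amplitude: 12 mm peak-to-peak excursion
    heart_amplitude: float = 0.0003  # sine amplitude: 0.6 mm peak-to-peak
    reflectivity: float = 1.0
    activity: str | None = None  # ground-truth label override
    # walker kinematics
    walk_speed: float = 0.5  # radial m/s, shuttling
    walk_span: float = 1.5  # corridor length in range, m
    stride_rate: float = 1.0  # Hz, limb oscillation
    limb_amplitude: float = 0.2  # m, limb range oscillation
    limb_reflectivity: float = 0.3  # relative to torso
    # fall kinematics
    fall_time: float = 10.0  # s, start of the fall event
    fall_duration: float = 1.0  # s
    fall_range_shift: float = 1.3  # m, radial excursion of the fall
    fall_rcs_gain: float = 4.0  # prone/broadside reflectivity gain
    # trunk model: precordial scatterer relative to the abdominal one
    precordial_offset: float = 0.12  # m, range separation
    precordial_resp_fraction: float = 0.1  # share of respiratory excursion
    precordial_reflectivity: float = 0.6  # relative to torso
    cardiac_harmonic_ratio: float = 0.2  # 2nd/1st harmonic of the apex impulse

    def __post_init__(self) -> None:
        if self.kind not in LIVING_KINDS + ("static_clutter",):
            raise SceneError(f"unknown actor kind {self.kind!r}")
        if self.is_living and not self.resp_amplitude > self.heart_amplitude > 0:
            raise SceneError("living actors need resp_amplitude > heart_amplitude > 0")

    @property
    def is_living(self) -> bool:
        return self.kind in LIVING_KINDS

    @property
    def fall_peak_speed(self) -> float:
        """Peak radial speed (m/s) of the raised-cosine fall transition."""
        return math.pi * abs(self.fall_range_shift) / (2.0 * self.fall_duration)


@dataclass(frozen=True)
class Interference:
    """Narrowband interferer: a fast-time sinusoid with per-scan random phase."""

    frequency_ghz: float
    amplitude: float


@dataclass(frozen=True)
class SceneScript:
    """A reproducible scene: actors + noise + interference + seed."""

    actors: tuple[Actor, ...] = ()
    duration: float = 60.0
    noise_sigma: float = 0.2  # fast-time sample noise std at 64-pulse integration
    interference: Interference | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise SceneError("duration must be positive")
        object.__setattr__(self, "actors", tuple(self.actors))


def chest_displacement(t, actor: Actor):
    """Radial chest-wall displacement (m) of a living actor at time t (s)."""
    if not actor.is_living:
        raise SceneError("chest displacement is defined for living actors only")
    t = np.asarray(t, dtype=np.float64)
    return actor.resp_amplitude * np.sin(
        2.0 * np.pi * actor.rr / 60.0 * t
    ) + actor.heart_amplitude * np.sin(2.0 * np.pi * actor.hr / 60.0 * t)


def cardiac_impulse(t, actor: Actor):
    """Pulsatile precordial displacement (m): fundamental plus second
    harmonic, normalized so the peak excursion equals ``heart_amplitude``."""
    t = np.asarray(t, dtype=np.float64)
    r = actor.cardiac_harmonic_ratio
    theta = 2.0 * np.pi * actor.hr / 60.0 * t
    wave = np.sin(theta) + r * np.sin(2.0 * theta)
    grid = np.linspace(0.0, 2.0 * np.pi, 721)
    peak = np.max(np.abs(np.sin(grid) + r * np.sin(2.0 * grid)))
    return actor.heart_amplitude * wave / peak


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 transition for u in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def _shuttle(t: np.ndarray, start: float, span: float, speed: float) -> np.ndarray:
    """Triangular back-and-forth path over [start, start + span]."""
    if span <= 0 or speed == 0:
        return np.full_like(t, start)
    phase = np.abs(speed) * t / span
    tri = 1.0 - np.abs(1.0 - 2.0 * (phase % 1.0))  # 0..1..0
    return start + span * tri

def _torso_range(actor: Actor, t: np.ndarray) -> np.ndarray:
    """Kinematic torso range (m) vs slow time, without chest displacement."""
    if actor.kind in ("stationary_subject", "static_clutter"):
        return np.full_like(t, actor.base_range)
    if actor.kind == "walker":
        return _shuttle(t, actor.base_range, actor.walk_span, actor.walk_speed)
    # faller: walk until fall_time, raised-cosine transition, then immobile
    pre = _shuttle(t, actor.base_range, actor.walk_span, actor.walk_speed)
    fall_start_range = _shuttle(
        np.asarray([actor.fall_time]), actor.base_range, actor.walk_span, actor.walk_speed
    )[0]
    u = (t - actor.fall_time) / actor.fall_duration
    transition = fall_start_range + actor.fall_range_shift * _raised_cosine(u)
    return np.where(t < actor.fall_time, pre, transition)


def _reflectivity(actor: Actor, t: np.ndarray) -> np.ndarray:
    refl = np.full_like(t, actor.reflectivity)
    if actor.kind == "faller":
        # the torso rotates broadside during the descent: the radar cross
        # section reaches its prone value by mid-fall and stays there
        u = 2.0 * (t - actor.fall_time) / actor.fall_duration
        gain = 1.0 + (actor.fall_rcs_gain - 1.0) * _raised_cosine(u)
        refl = refl * np.where(t < actor.fall_time, 1.0, gain)
    return refl


def _activity(actor: Actor, t: np.ndarray) -> np.ndarray:
    if actor.activity is not None:
        return np.full(t.shape, actor.activity, dtype=object)
    if actor.kind == "stationary_subject":
        return np.full(t.shape, "sitting", dtype=object)
    if actor.kind == "walker":
        return np.full(t.shape, "walking", dtype=object)
    if actor.kind == "faller":
        lab = np.full(t.shape, "walking", dtype=object)
        lab[t >= actor.fall_time] = "fall"
        lab[t >= actor.fall_time + actor.fall_duration] = "post-fall"
        return lab
    return np.full(t.shape, "none", dtype=object)


def _scatterers(actor: Actor, t: np.ndarray):
    """Yield (range_series, reflectivity_series) for each point scatterer."""
    torso = _torso_range(actor, t)
    refl = _reflectivity(actor, t)
    if actor.is_living:
        yield torso + chest_displacement(t, actor), refl
        resp = actor.resp_amplitude * np.sin(2.0 * np.pi * actor.rr / 60.0 * t)
        precordial = (
            torso
            + actor.precordial_offset
            + actor.precordial_resp_fraction * resp
            + cardiac_impulse(t, actor)
        )
        yield precordial, refl * actor.precordial_reflectivity
    else:
        yield torso, refl
    moving = actor.kind in ("walker", "faller")
    if actor.is_living and moving and actor.limb_amplitude > 0:
        swing = actor.limb_amplitude * np.sin(2.0 * np.pi * actor.stride_rate * t)
        if actor.kind == "faller":
            # limbs stop swinging once the body is down
            swing = np.where(t < actor.fall_time + actor.fall_duration, swing, 0.0)
        limb_refl = refl * actor.limb_reflectivity
        yield torso + swing, limb_refl
        yield torso - swing, limb_refl


def render_scans(
    scene: SceneScript, timing: TimingPlan, pulse: PulseModel = PULSE
) -> tuple[ScanMatrix, pd.DataFrame]:
    """Render a scene into a scan matrix plus a per-scan ground-truth table.

    Each scan is the superposition of every scatterer's pulse echo at its
    instantaneous two-way delay, plus white Gaussian fast-time noise whose
    standard deviation is ``noise_sigma`` reduced by the rake-integration
    gain beyond the 64-pulse baseline, plus optional narrowband interference.
    Bit-reproducible for a fixed scene seed.
    """
    n_scans = int(round(scene.duration * timing.fs))
    if n_scans < 1:
        raise SceneError("scene too short for a single scan")
    t = np.arange(n_scans) / timing.fs
    fast_time = timing.fast_time_axis()  # ns
    c = timing.constants.c
    rng = np.random.default_rng(scene.seed)

    # noise and interference are drawn before actors are rendered so that
    # scenes differing only in actors share identical noise realizations
    samples = np.zeros((n_scans, timing.n_bins))
    if scene.noise_sigma > 0:
        extra_gain_db = snr_gain_db(2**timing.pii) - snr_gain_db(64)
        sigma = scene.noise_sigma * 10.0 ** (-extra_gain_db / 20.0)
        samples += rng.normal(0.0, sigma, size=samples.shape)
    if scene.interference is not None:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_scans)
        amps = scene.interference.amplitude * rng.uniform(0.5, 1.0, size=n_scans)
        samples += amps[:, None] * np.cos(
            2.0 * np.pi * scene.interference.frequency_ghz * fast_time[None, :]
            + phases[:, None]
        )

    margin = 4.0 * pulse.sigma_ns * c / 2.0
    for actor in scene.actors:
        for ranges, refl in _scatterers(actor, t):
            if ranges.min() < timing.r1 - margin or ranges.max() > timing.r2 + margin:
                raise SceneError(
                    f"actor {actor.kind!r} leaves the range window "
                    f"[{timing.r1:.2f}, {timing.r2:.2f}] m"
                )
            delay = timing.constants.min_fast_time_ns + 2.0 * ranges / c  # ns
            samples += refl[:, None] * pulse(fast_time[None, :] - delay[:, None])

    truth = _ground_truth(scene, t)
    return ScanMatrix(samples, timing, seed=scene.seed), truth


def _ground_truth(scene: SceneScript, t: np.ndarray) -> pd.DataFrame:
    living = [a for a in scene.actors if a.is_living]
    n = len(t)
    if not living:
        return pd.DataFrame(
            {
                "scan_index": np.arange(n),
                "time_s": t,
                "range_m": np.nan,
                "hr_bpm": np.nan,
                "rr_brpm": np.nan,
                "activity": "none",
                "people_count": 0,
            },
            columns=GROUND_TRUTH_COLUMNS,
        )
    ranges = np.stack([_torso_range(a, t) for a in living])  # (n_living, n)
    nearest = np.argmin(ranges, axis=0)
    idx = np.arange(n)
    activities = np.stack([_activity(a, t) for a in living])
    return pd.DataFrame(
        {
            "scan_index": idx,
            "time_s": t,
            "range_m": ranges[nearest, idx],
            "hr_bpm": np.array([a.hr for a in living])[nearest],
            "rr_brpm": np.array([a.rr for a in living])[nearest],
            "activity": activities[nearest, idx],
            "people_count": len(living),
        },
        columns=GROUND_TRUTH_COLUMNS,
    )


ADL_BLOCK_MINUTES = 12  # a behavioural "episode": same activity profile


def adl_scene(
    seed: int,
    minute: int = 0,
    duration: float = 60.0,
    noise_sigma: float = 0.2,
) -> SceneScript:
    """One activities-of-daily-living minute of a monitored person.

    A person's routine is not stationary minute to minute: activities come
    in episodes (cooking, tidying, resting, exercising) whose intensity and
    location differ.  Minutes are therefore grouped into blocks of
    ``ADL_BLOCK_MINUTES`` sharing an activity profile (walking-speed centre,
    room region, sitting propensity) drawn from a continuum, with
    minute-level jitter around it.  A short observation window samples few
    episodes of the repertoire; a long one covers it — which is what makes
    longer unsupervised calibration genuinely more informative.
    """
    block_rng = np.random.default_rng([seed, minute // ADL_BLOCK_MINUTES])
    speed_centre = block_rng.uniform(0.25, 1.1)
    span_centre = block_rng.uniform(0.4, 0.9)
    sitting_prob = block_rng.uniform(0.2, 0.7)
    stride_centre = block_rng.uniform(0.7, 1.6)

    rng = np.random.default_rng([seed, minute, 7919])
    if rng.random() >= sitting_prob:
        subject = Actor(
            kind="walker",
            base_range=float(rng.uniform(0.8, 1.1)),
            walk_span=float(np.clip(span_centre + rng.uniform(-0.1, 0.1), 0.3, 1.0)),
            walk_speed=float(np.clip(speed_centre + rng.uniform(-0.1, 0.1), 0.15, 1.2)),
            stride_rate=float(np.clip(stride_centre + rng.uniform(-0.2, 0.2), 0.5, 2.0)),
            rr=float(rng.uniform(12, 20)),
            hr=float(rng.uniform(60, 90)),
        )
    else:
        subject = Actor(
            kind="stationary_subject",
            base_range=float(rng.uniform(1.0, 2.4)),
            rr=float(rng.uniform(12, 20)),
            hr=float(rng.uniform(60, 90)),
            activity=str(rng.choice(["sitting", "cooking-like motion"])),
        )
    clutter = Actor(
        kind="static_clutter",
        base_range=float(rng.uniform(2.6, 3.0)),
        reflectivity=float(rng.uniform(5.0, 15.0)),
    )
    return SceneScript(
        actors=(subject, clutter),
        duration=duration,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(2**31 - 1)),
    )


def fall_scene(seed: int, duration: float = 25.0, noise_sigma: float = 0.2) -> SceneScript:
    """A scripted fall: walking, a ~1 s fall transition with peak radial
    speed above 2 m/s, then post-fall immobility with vitals only.  Returns
    a scene whose faller actor exposes ``fall_time`` for ground truth."""
    rng = np.random.default_rng(seed)
    faller = Actor(
        kind="faller",
        base_range=float(rng.uniform(0.8, 1.0)),
        walk_span=float(rng.uniform(0.4, 0.6)),
        walk_speed=float(rng.uniform(0.4, 0.7)),
        fall_time=float(rng.uniform(6.0, 10.0)),
        fall_duration=float(rng.uniform(0.8, 1.2)),
        fall_range_shift=1.3,
        rr=float(rng.uniform(12, 20)),
        hr=float(rng.uniform(60, 90)),
    )
    clutter = Actor(
        kind="static_clutter",
        base_range=float(rng.uniform(2.6, 3.0)),
        reflectivity=float(rng.uniform(5.0, 15.0)),
    )
    return SceneScript(
        actors=(faller, clutter),
        duration=duration,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(2**31 - 1)),
    )


def add_narrowband_interference(
    scan: ScanMatrix, frequency_ghz: float, amplitude: float, seed: int = 0
) -> ScanMatrix:
    """Add a fast-time sinusoid with per-scan random phase; amplitude 0 is a
    no-op and the operation is invertible by subtracting the same tone."""
    if amplitude == 0:
        return scan.with_samples(scan.samples.copy())
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=scan.n_scans)
    tone = amplitude * np.cos(
        2.0 * np.pi * frequency_ghz * scan.timing.fast_time_axis()[None, :]
        + phases[:, None]
    )
    return scan.with_samples(scan.samples + tone)
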