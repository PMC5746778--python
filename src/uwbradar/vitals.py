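"""Heart- and respiration-rate estimation via empirical mode decomposition.

Chest-wall motion modulates the radar return at the respiration (~0.2-0.5 Hz)
and heartbeat (~1-2 Hz) frequencies, but the respiratory displacement is
roughly twenty times the cardiac one, so plain spectral filtering cannot
separate them.  After a 6th-order slow-time Butterworth bandpass
(0.125-3 Hz, i.e. 7.5 breaths/min to 180 beats/min), each range-gated
slow-time series is decomposed by EMD: cubic-spline envelopes through the
local extrema are averaged, the local detail is peeled off, and the process
repeats until the detail satisfies the intrinsic-mode conditions (extrema
and zero-crossing counts differ by at most one, envelope mean near zero).
Each mode receives the weight w = ||pdf(s) - pdf(mode)||_2 comparing
histogram-approximated amplitude densities; along the mode index the weights
rise over the noisy modes, then fall to a minimum at the modes that carry
the cardiorespiratory signal.  The modes on that descending run are kept,
their mean frequencies (zero-crossing rate) computed, and assigned to RR or
HR by physiological band; the rates are medians across the range bins of the
current movement region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.interpolate import CubicSpline

from .io import ScanMatrix
from .micromotion import MovementRegion

__all__ = [
    "VitalsBandpassSpec",
    "EMDStopCriterion",
    "IMFDecomposition",
    "VitalsEstimate",
    "VitalsError",
    "design_slowtime_bandpass",
    "apply_slowtime_filter",
    "sift",
    "imf_weight",
    "select_imfs",
    "selected_mode_run",
    "mean_frequency",
    "estimate_rates",
]

RR_BAND_HZ = (0.125, 0.7)  # 7.5 - 42 breaths/min
HR_BAND_HZ = (0.7, 3.0)  # 42 - 180 beats/min


class VitalsError(ValueError):
    pass


@dataclass(frozen=True)
class VitalsBandpassSpec:
    """Slow-time Butterworth bandpass: 0.125 Hz (7.5 breaths/min) to 3 Hz
    (180 beats/min), order 6, ~0.8 Hz stopband width."""

    order: int = 6
    passband_hz: tuple[float, float] = (0.125, 3.0)
    stopband_width_hz: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.passband_hz[0] < self.passband_hz[1]:
            raise VitalsError("passband edges must be positive and increasing")


def design_slowtime_bandpass() -> VitalsBandpassSpec:
    return VitalsBandpassSpec()


def slowtime_sos(spec: VitalsBandpassSpec, fs: float) -> np.ndarray:
    if spec.passband_hz[1] >= fs / 2:
        raise VitalsError("passband exceeds the slow-time Nyquist rate")
    return _signal.butter(
        spec.order // 2, list(spec.passband_hz), btype="bandpass", fs=fs, output="sos"
    )


def apply_slowtime_filter(
    scan: ScanMatrix, spec: VitalsBandpassSpec | None = None
) -> ScanMatrix:
    """Zero-phase slow-time bandpass of every range bin."""
    spec = spec or design_slowtime_bandpass()
    sos = slowtime_sos(spec, scan.timing.fs)
    return scan.with_samples(_signal.sosfiltfilt(sos, scan.samples, axis=0))


@dataclass(frozen=True)
class EMDStopCriterion:
    """Sifting controls: envelope-mean threshold (relative to the envelope
    half-width), iteration cap per mode, mode-count cap, and the number of
    consecutive iterations the intrinsic-mode conditions must persist before
    a detail is accepted (guards against under-sifted, mode-mixed IMFs)."""

    mean_threshold: float = 0.05
    max_sift_iterations: int = 100
    max_modes: int = 12
    s_number: int = 15

    def __post_init__(self) -> None:
        if (
            min(
                self.mean_threshold,
                self.max_sift_iterations,
                self.max_modes,
                self.s_number,
            )
            <= 0
        ):
            raise VitalsError("stop-criterion fields must be positive")


@dataclass
class IMFDecomposition:
    """Ordered intrinsic mode functions, residue and per-mode weights."""

    modes: list[np.ndarray]
    residue: np.ndarray
    weights: np.ndarray | None = None
    source_range_bin: int | None = None

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for m in self.modes:
            out += m
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima (plateau midpoints)."""
    dx = np.diff(x)
    sgn = np.sign(dx)
    # propagate the previous slope through flat runs so plateaus count once
    for i in range(1, sgn.size):
        if sgn[i] == 0:
            sgn[i] = sgn[i - 1]
    turns = np.diff(sgn)
    maxima = np.nonzero(turns < 0)[0] + 1
    minima = np.nonzero(turns > 0)[0] + 1
    return maxima, minima


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[:-1] != s[1:]))


def _envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through the extrema, mirror-extended at the ends
    to tame the spline's boundary swing."""
    t = idx.astype(float)
    v = x[idx]
    k = min(2, idx.size)
    if k > 0:
        # extrema are interior (idx >= 1), so reflections about the series
        # endpoints never collide with the originals
        left_t, left_v = -t[:k][::-1], v[:k][::-1]
        right_t, right_v = 2.0 * (n - 1) - t[-k:][::-1], v[-k:][::-1]
        t = np.concatenate([left_t, t, right_t])
        v = np.concatenate([left_v, v, right_v])
    spline = CubicSpline(t, v, bc_type="natural")
    return spline(np.arange(n))


def sift(s: np.ndarray, crit: EMDStopCriterion | None = None) -> IMFDecomposition:
    """Empirical mode decomposition of one slow-time series.

    Modes are peeled highest-frequency first; decomposition ends when the
    residual has fewer than two maxima or minima (monotone trend) or
    ``max_modes`` is reached.  The sum of the modes plus the residue equals
    the input to floating-point accuracy by construction.
    """
    crit = crit or EMDStopCriterion()
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 1 or s.size < 8:
        raise VitalsError("need a 1-D series of at least 8 samples")
    n = s.size
    modes: list[np.ndarray] = []
    residue = s.copy()
    for _ in range(crit.max_modes):
        maxima, minima = _local_extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residue.copy()
        streak = 0
        for _ in range(crit.max_sift_iterations):
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            upper = _envelope(h, maxima, n)
            lower = _envelope(h, minima, n)
            m = (upper + lower) / 2.0
            h = h - m
            n_extrema = maxima.size + minima.size
            n_zc = _count_zero_crossings(h)
            half_width = np.mean(np.abs(upper - lower)) / 2.0
            mean_small = half_width == 0 or (
                np.mean(np.abs(m)) < crit.mean_threshold * half_width
            )
            streak = streak + 1 if (abs(n_extrema - n_zc) <= 1 and mean_small) else 0
            if streak >= crit.s_number:
                break
        modes.append(h)
        residue = residue - h
    return IMFDecomposition(modes=modes, residue=residue)


def imf_weight(s: np.ndarray, f: np.ndarray, bin_width: float) -> float:
    """L2 distance between the histogram PDFs of a source series and a mode.

    Histograms share a common support (the union of both ranges) and the
    given bin width (max std over the source series, divided by 4); counts
    are normalized to densities so the distance is a function-space L2 norm.
    """
    s = np.asarray(s, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if np.ptp(s) == 0 or np.ptp(f) == 0:
        raise VitalsError("degenerate (constant) series has no usable PDF")
    if bin_width <= 0:
        raise VitalsError("bin width must be positive")
    lo = min(s.min(), f.min())
    hi = max(s.max(), f.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    p, _ = np.histogram(s, bins=edges, density=True)
    q, _ = np.histogram(f, bins=edges, density=True)
    return float(np.sqrt(np.sum((p - q) ** 2) * bin_width))


def _last_noisy_maximum(weights: np.ndarray) -> int | None:
    """Index of the last local maximum of the weight sequence (the last noisy
    mode), treating the first element as a maximum when it dominates its
    neighbour.  None when the sequence is monotone non-decreasing up to the
    end or has no descending tail."""
    w = np.asarray(weights, dtype=np.float64)
    maxima = []
    if w.size >= 2 and w[0] > w[1]:
        maxima.append(0)
    for i in range(1, w.size - 1):
        if w[i - 1] < w[i] and w[i] > w[i + 1]:
            maxima.append(i)
    if not maxima:
        return None
    return maxima[-1]


def select_imfs(weights: np.ndarray) -> int:
    """Index (0-based) of the single best mode for one scan.

    The weight subsequence rises over the noisy modes and falls to its
    minimum at the mode that best matches the source PDF: take the minimum
    after the last local maximum.  A monotone-decreasing sequence has no
    noisy prefix, so the global minimum is returned; ties break toward the
    lower index (the higher-frequency mode).
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.size < 2:
        if w.size == 1:
            return 0
        raise VitalsError("need at least one weight")
    last_max = _last_noisy_maximum(w)
    start = 0 if last_max is None else last_max + 1
    if start >= w.size:  # weights end on a rise; fall back to the global minimum
        return int(np.argmin(w))
    return start + int(np.argmin(w[start:]))


def selected_mode_run(weights: np.ndarray, descent_tol: float = 0.15) -> list[int]:
    """All mode indices on the descending run that ends at the minimum
    weight: the weight sequence rises over the noisy modes, peaks at the
    last noisy one, then falls through the modes that best describe the
    cardiorespiratory signal (typically the cardiac mode followed by the
    respiratory one).  Walking back from the global minimum, a step counts
    as part of the descent when the earlier weight is not more than
    ``descent_tol`` below the later one (weights of low-energy modes are
    noisy, and a strict comparison would cut the run at spurious 1% bumps);
    a genuinely prominent preceding maximum is excluded from the run."""
    w = np.asarray(weights, dtype=np.float64)
    if w.size == 0:
        raise VitalsError("need at least one weight")
    m_star = int(np.argmin(w))
    start = m_star
    while start > 0 and w[start - 1] >= w[start] * (1.0 - descent_tol):
        start -= 1
    # if the run's top is itself a prominent peak (a genuine drop follows it
    # and an ascent, or the boundary, precedes it) it is the last noisy mode
    # and stays excluded
    if (
        start < m_star
        and w[start] > w[start + 1] * (1.0 + descent_tol)
        and (start == 0 or w[start - 1] < w[start])
    ):
        start += 1
    return list(range(start, m_star + 1))


def _zero_crossing_indices(x: np.ndarray, band: float) -> np.ndarray:
    """Sample indices of zero crossings, with a +/- dead band around zero: a
    crossing registers only when the signal passes from beyond one side of
    the band to beyond the other, so noise wiggles at shallow crossings
    count once."""
    state = 0
    out = []
    for i, v in enumerate(x):
        if v > band:
            if state == -1:
                out.append(i)
            state = 1
        elif v < -band:
            if state == 1:
                out.append(i)
            state = -1
    return np.asarray(out)


def _zero_crossing_rate(x: np.ndarray, fs: float, band: float) -> float:
    """Unbiased mean frequency from zero crossings: (n-1) half-periods span
    the interval between the first and last crossing, avoiding the edge
    truncation and 1/(2T) quantization of a plain count over the window."""
    idx = _zero_crossing_indices(x, band)
    if idx.size >= 3:
        return (idx.size - 1) * fs / (2.0 * (idx[-1] - idx[0]))
    duration = x.size / fs
    return idx.size / (2.0 * duration)


def mean_frequency(
    mode: np.ndarray,
    fs: float,
    method: str = "zero_crossing",
    hysteresis: float = 0.2,
) -> float:
    """Average frequency (Hz) of a mode: zero-crossing count over twice the
    duration (default), or the mean Hilbert instantaneous frequency.

    ``hysteresis`` (zero-crossing method only) sets the dead band around
    zero as a fraction of the mode's standard deviation; 0 counts every
    sign change.
    """
    mode = np.asarray(mode, dtype=np.float64)
    if method == "zero_crossing":
        band = hysteresis * mode.std() if mode.std() > 0 else 0.0
        return _zero_crossing_rate(mode, fs, band)
    if method == "hilbert":
        analytic = _signal.hilbert(mode)
        phase = np.unwrap(np.angle(analytic))
        inst = np.diff(phase) * fs / (2.0 * np.pi)
        return float(np.mean(inst))
    raise VitalsError(f"unknown mean-frequency method {method!r}")


def _band_coherence(mode: np.ndarray, freq: float, fs: float, rel_width: float = 0.35) -> float:
    """Fraction of a mode's spectral energy within +/- ``rel_width`` of its
    nominal frequency.  An intrinsic mode with a well-defined instantaneous
    frequency concentrates its energy there; a mode-mixed artefact whose
    zero-crossing rate sits between its true components does not."""
    if not np.isfinite(freq) or freq <= 0:
        return 0.0
    spectrum = np.abs(np.fft.rfft(mode)) ** 2
    total = spectrum.sum()
    if total == 0:
        return 0.0
    f = np.fft.rfftfreq(mode.size, 1.0 / fs)
    sel = (f >= freq * (1.0 - rel_width)) & (f <= freq * (1.0 + rel_width))
    return float(spectrum[sel].sum() / total)


def _robust_mode_frequency(mode: np.ndarray, fs: float) -> tuple[float, float]:
    """Mode frequency by noise-adaptive zero-crossing counting.

    A first zero-crossing pass locates the mode's band; the RMS of the
    spectral energy outside that band sets the dead band for a second,
    hysteresis-guarded count, so noisy modes do not over-count crossings
    while clean low-frequency modes keep their genuine shallow crossings.
    Returns (frequency, band coherence).
    """
    sigma = mode.std()
    f0 = mean_frequency(mode, fs, hysteresis=0.0)
    if f0 <= 0 or sigma == 0:
        return f0, 0.0
    coh = _band_coherence(mode, f0, fs)
    # cardiac-band modes cross zero steeply but carry in-band noise that
    # multiplies shallow spurious crossings: a wide dead band removes those
    # without losing the genuine steep crossings.  Respiratory modes are the
    # opposite — their radar-amplitude waveform dwells near zero, so the
    # genuine crossings are shallow and only a narrow dead band is safe.
    band = (0.4 if f0 >= HR_BAND_HZ[0] else 0.15) * sigma
    if band > 0:
        f1 = _zero_crossing_rate(mode, fs, band)
        if f1 > 0:
            return f1, _band_coherence(mode, f1, fs)
    return f0, coh


def _fold_harmonics(freqs: list[float], bands, rel_tol: float = 0.12) -> list[float]:
    """Resolve the frequency-doubling ambiguity of envelope-detected motion.

    Where the carrier phase at a range bin is near even symmetry, the echo
    amplitude responds at twice the motion frequency, so the per-bin
    frequency candidates form fundamental/double pairs.  A candidate f is
    folded to f/2 when some other candidate sits near f/2 AND f/2 lies in
    the same physiological band as f (folding never crosses the RR/HR band
    edge, so a true cardiac fundamental cannot be mistaken for a
    respiratory harmonic).
    """
    freqs = list(freqs)

    def cluster_size(f0: float, skip: int) -> int:
        return sum(
            1
            for i, g in enumerate(freqs)
            if i != skip and abs(g - f0) <= rel_tol * f0
        )

    out = []
    for i, f in enumerate(freqs):
        half = f / 2.0
        same_band = any(lo <= f < hi and lo <= half < hi for lo, hi in bands)
        # fold toward the fundamental only when more bins agree on it than on
        # the doubled reading itself
        if same_band and cluster_size(half, i) > cluster_size(f, i):
            out.append(half)
        else:
            out.append(f)
    return out


@dataclass
class VitalsEstimate:
    """HR (beats/min) and RR (breaths/min) over one observation window.

    Missing estimates are NaN with the corresponding flag set; the
    ``movement`` flag marks windows whose movement amplitude renders the
    cardiac estimate low-confidence.
    """

    hr: float
    rr: float
    window: tuple[float, float]
    flags: dict = field(default_factory=dict)

    @property
    def hr_missing(self) -> bool:
        return not np.isfinite(self.hr)

    @property
    def rr_missing(self) -> bool:
        return not np.isfinite(self.rr)


def estimate_rates(
    scan: ScanMatrix,
    region: MovementRegion,
    window: tuple[float, float] | None = None,
    crit: EMDStopCriterion | None = None,
    max_bins: int = 24,
    movement_amplitude: float | None = None,
    movement_flag_threshold: float | None = None,
    band_split_hz: float = RR_BAND_HZ[1],
    energy_gate: float = 0.1,
    coherence_gate: float = 0.5,
) -> VitalsEstimate:
    """Estimate HR and RR from the clutter-free, slow-time-filtered scans.

    Range bins inside the movement region (subsampled to ``max_bins``) are
    EMD-decomposed; each bin's modes are weighted by PDF distance with a
    common histogram bin width (max std over the bins, / 4), the descending-
    run modes are selected, and each selected mode's mean frequency is
    assigned to RR (below ``band_split_hz``) or HR (above it); each vital is
    the median of its candidates across bins.
    """
    crit = crit or EMDStopCriterion()
    t = scan.slow_time_axis()
    if window is None:
        window = (float(t[0]), float(t[-1]) + 1.0 / scan.timing.fs)
    mask = (t >= window[0]) & (t < window[1])
    if mask.sum() < 10 * scan.timing.fs:
        raise VitalsError("observation window must span at least 10 s")
    cols = region.bin_slice(scan.range_axis())
    sub = scan.samples[mask, cols]
    # bins whose slow-time variation is far below the region maximum carry no
    # body return: with the shared histogram bin width their amplitudes all
    # land in one bin and every mode weight degenerates to zero, so drop them
    col_stds = sub.std(axis=0)
    if col_stds.max() > 0:
        sub = sub[:, col_stds >= energy_gate * col_stds.max()]
    n_cols = sub.shape[1]
    take = np.unique(np.linspace(0, n_cols - 1, min(max_bins, n_cols)).astype(int))
    series = [sub[:, j] for j in take]
    stds = [s.std() for s in series]
    bin_width = max(stds) / 4.0 if max(stds) > 0 else 0.0

    candidates: list[float] = []
    duration = mask.sum() / scan.timing.fs
    for s in series:
        if s.std() == 0 or bin_width == 0:
            continue
        dec = sift(s, crit)
        if not dec.modes:
            continue
        weights = np.array(
            [
                imf_weight(s, m, bin_width) if np.ptp(m) > 0 else np.inf
                for m in dec.modes
            ]
        )
        dec.weights = weights
        finite = np.isfinite(weights)
        if not finite.any():
            continue
        run = selected_mode_run(np.where(finite, weights, weights[finite].max() + 1))
        # the weight minimum marks the mode closest in distribution to the
        # source (respiration); the cardiac mode sits one step above it on
        # the descending segment, so the run's immediate shoulder is pooled
        # too — the coherence gate, band assignment and harmonic folding
        # discard non-physiological entries
        if run and run[0] > 0:
            run = [run[0] - 1] + run
        for j in run:
            freq, coherence = _robust_mode_frequency(dec.modes[j], scan.timing.fs)
            if coherence >= coherence_gate:
                candidates.append((freq, coherence))

    bands = ((RR_BAND_HZ[0], band_split_hz), (band_split_hz, HR_BAND_HZ[1]))
    folded = _fold_harmonics([f for f, _ in candidates], bands)
    coherences = [c for _, c in candidates]

    def band_median(lo: float, hi: float) -> float:
        members = [
            (f, c) for f, c in zip(folded, coherences) if lo <= f < hi
        ]
        if not members:
            return float("nan")
        # strongly coherent modes carry the vital cleanly; fall back to the
        # whole pool only when no such mode exists in the band
        strong = [f for f, c in members if c >= 0.75]
        pool = strong if strong else [f for f, _ in members]
        return float(np.median(pool)) * 60.0

    rr_value = band_median(*bands[0])
    hr_value = band_median(bands[1][0], bands[1][1] + 1e-9)
    rr_candidates = [f * 60.0 for f in folded if bands[0][0] <= f < bands[0][1]]
    hr_candidates = [f * 60.0 for f in folded if bands[1][0] <= f <= bands[1][1]]

    flags = {
        "hr_missing": not hr_candidates,
        "rr_missing": not rr_candidates,
        "n_bins_used": len(series),
        "window_duration_s": duration,
    }
    if movement_amplitude is not None and movement_flag_threshold is not None:
        flags["movement"] = movement_amplitude > movement_flag_threshold
    return VitalsEstimate(hr=hr_value, rr=rr_value, window=window, flags=flags)
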