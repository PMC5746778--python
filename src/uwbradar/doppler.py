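"""Micro-Doppler spectrogram over (frame, Doppler frequency, range).

Per range bin, the clutter-free slow-time signal is made analytic (Hilbert
transform supplies the imaginary part) and short discrete-time Fourier
transforms are taken over 50%-overlapped frames of 16 scans (320 ms at the
50 Hz slow-time rate).  The frequency axis is centred: positive Doppler
means an approaching target, since a shrinking two-way delay advances the
carrier phase of the slow-time return.  Transforms are orthonormal so each
frame/range column conserves the analytic-signal frame energy (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.fft import fft, fftshift, fftfreq

from .io import ScanMatrix

__all__ = [
    "SpectrogramSpec",
    "DopplerSpectrogram",
    "analytic_signal",
    "doppler_spectrogram",
]


@dataclass(frozen=True)
class SpectrogramSpec:
    """Framing of the slow-time DTFT.

    n_dtft scans per frame (default 16), fractional overlap (default 0.5),
    slow-time rate fr (Hz).  Doppler bin width is fr/n_dtft = 3.125 Hz at
    the defaults.  ``window`` is "rectangular" (default; none is applied) or
    "hann".
    """

    n_dtft: int = 16
    overlap: float = 0.5
    fr: float = 50.0
    window: str = "rectangular"

    def __post_init__(self) -> None:
        if self.n_dtft < 2:
            raise ValueError("n_dtft must be >= 2")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if self.window not in ("rectangular", "hann"):
            raise ValueError("window must be 'rectangular' or 'hann'")

    @property
    def frame_duration(self) -> float:
        """T_DTFT = n_dtft / fr, in seconds."""
        return self.n_dtft / self.fr

    @property
    def hop(self) -> int:
        return max(1, int(round(self.n_dtft * (1.0 - self.overlap))))

    @property
    def bin_width_hz(self) -> float:
        return self.fr / self.n_dtft


@dataclass
class DopplerSpectrogram:
    """Magnitudes over (frame, Doppler bin, range bin) with labelled axes."""

    magnitude: np.ndarray  # (n_frames, n_dtft, n_bins), non-negative
    frequencies: np.ndarray  # Hz, centred, length n_dtft
    range_axis: np.ndarray  # m, length n_bins
    frame_times: np.ndarray  # s, frame centres
    spec: SpectrogramSpec

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    def frame_energy(self) -> np.ndarray:
        """Total spectral energy per (frame, range bin)."""
        return np.sum(self.magnitude**2, axis=1)


def analytic_signal(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Analytic version of a real signal: real part is the input exactly,
    negative-frequency content is suppressed."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[axis] < 4:
        raise ValueError("need at least 4 samples along the transform axis")
    return _signal.hilbert(x, axis=axis)


def doppler_spectrogram(
    scan: ScanMatrix, spec: SpectrogramSpec | None = None
) -> DopplerSpectrogram:
    """Short-time Doppler analysis of a (clutter-free) scan matrix."""
    spec = spec or SpectrogramSpec(fr=scan.timing.fs)
    n, hop = spec.n_dtft, spec.hop
    freqs = fftshift(fftfreq(n, d=1.0 / spec.fr))
    if scan.n_scans < n:
        return DopplerSpectrogram(
            magnitude=np.zeros((0, n, scan.n_bins)),
            frequencies=freqs,
            range_axis=scan.range_axis(),
            frame_times=np.zeros(0),
            spec=spec,
        )
    analytic = analytic_signal(scan.samples, axis=0)
    starts = np.arange(0, scan.n_scans - n + 1, hop)
    frames = np.stack([analytic[s : s + n] for s in starts])  # (F, n, bins)
    if spec.window == "hann":
        win = np.hanning(n)
        win = win / np.sqrt(np.mean(win**2))  # keep Parseval scaling
        frames = frames * win[None, :, None]
    spectra = fftshift(fft(frames, axis=1, norm="ortho"), axes=1)
    slow_t = scan.slow_time_axis()
    centres = slow_t[starts] + (n - 1) / (2.0 * spec.fr)
    return DopplerSpectrogram(
        magnitude=np.abs(spectra),
        frequencies=freqs,
        range_axis=scan.range_axis(),
        frame_times=centres,
        spec=spec,
    )
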