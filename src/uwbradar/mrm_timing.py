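"""Acquisition timing for the monostatic UWB impulse-radar module.

The radar front end (a PulsON P410-class monostatic radar module, MRM)
quantizes the fast-time axis in hardware: samples are produced by a rake
receiver whose fine sampler quantum is 1 us / 2**19 = 1.9073486 ps, scans are
assembled from *stack segments* of 96 samples spanning 5.8594 ns each
(~0.878 m of one-way range), and the earliest usable fast-time instant is
10 ns.  A desired range window [R1~, R2~] therefore maps to an *actual*
window [R1, R2] through a chain of floor/ceil quantizations.  This module
implements that chain and the rake-integration SNR model, producing a
:class:`TimingPlan` that the simulator and the processing stages share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PhysicalConstants",
    "DesiredRange",
    "TimingPlan",
    "TimingError",
    "compute_scan_bins",
    "compute_t1",
    "compute_t2",
    "compute_actual_range",
    "compute_scan_duration",
    "compute_idle_time",
    "snr_gain_db",
    "derive_timing",
]


class TimingError(ValueError):
    """Raised for infeasible or out-of-domain timing requests."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Hardware constants of the radar module.

    Attributes
    ----------
    c : speed of light in m/ns.
    bin_duration_ps : fine sampler bin in ps.  The hardware quantum is
        1 us / 2**19 = 1.9073486... ps; datasheets round it to 1.9073.
        The exact value reproduces the reference acquisition table to the
        printed precision, the rounded one is a fine-bin low in T1/T2.
    sample_step_ps : fast-time spacing of emitted scan samples,
        32 fine bins = 61.035 ps.
    segment_duration_ns : duration of one stack segment (96 samples).
    bins_per_segment : scan samples per stack segment.
    base_scan_slot_us : slow-time cost of scanning one segment once.
    min_fast_time_ns : earliest fast-time instant the module accepts.
    """

    c: float = 0.29979
    bin_duration_ps: float = 1e6 / 2**19  # 1.9073486...
    sample_step_ps: float = 32 * 1e6 / 2**19  # 61.035...
    segment_duration_ns: float = 5.8594
    bins_per_segment: int = 96
    base_scan_slot_us: float = 0.792
    min_fast_time_ns: float = 10.0

    def __post_init__(self) -> None:
        seg = self.bins_per_segment * self.sample_step_ps / 1000.0
        if abs(seg - self.segment_duration_ns) > 1e-3 * self.segment_duration_ns:
            raise TimingError(
                "bins_per_segment * sample_step inconsistent with segment duration"
            )


CONSTANTS = PhysicalConstants()

PII_MIN, PII_MAX = 6, 15


@dataclass(frozen=True)
class DesiredRange:
    """Requested range window [r1_desired, r2_desired] in metres."""

    r1_desired: float
    r2_desired: float

    def __post_init__(self) -> None:
        if not 0 < self.r1_desired < self.r2_desired:
            raise TimingError(
                f"need 0 < r1 < r2, got ({self.r1_desired}, {self.r2_desired})"
            )


@dataclass(frozen=True)
class TimingPlan:
    """Fully derived acquisition parameters for one radar configuration.

    ``n_bins`` scan samples cover fast times [t1, t2] ns i.e. ranges
    [r1, r2] m; a scan takes ``ts`` us followed by ``ti`` us of idle so that
    the slow-time sampling frequency is ``fs`` Hz.
    """

    n_bins: int
    t1: float
    t2: float
    r1: float
    r2: float
    ts: float
    ti: float
    pii: int
    fs: float
    constants: PhysicalConstants = field(default=CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        if self.n_bins <= 0 or self.n_bins % self.constants.bins_per_segment:
            raise TimingError("n_bins must be a positive multiple of 96")
        if not self.t2 > self.t1 >= self.constants.min_fast_time_ns:
            raise TimingError("need t2 > t1 >= 10 ns")
        if not self.r2 > self.r1 >= 0:
            raise TimingError("need r2 > r1 >= 0")
        if self.ts <= 0:
            raise TimingError("scan duration must be positive")
        period = 1e6 / self.fs
        if abs(self.ts + self.ti - period) > 1e-6 * period:
            raise TimingError("ts + ti must equal the slow-time sampling period")

    @property
    def sample_step_ns(self) -> float:
        """Fast-time spacing between consecutive scan samples, in ns."""
        return self.constants.sample_step_ps / 1000.0

    def fast_time_axis(self):
        """Fast-time instants (ns) of the n_bins scan samples."""
        import numpy as np

        return self.t1 + np.arange(self.n_bins) * self.sample_step_ns

    def range_axis(self):
        """One-way range (m) associated with each scan sample."""
        c = self.constants.c
        return c / 2.0 * (self.fast_time_axis() - self.constants.min_fast_time_ns)


def compute_scan_bins(desired: DesiredRange, constants: PhysicalConstants = CONSTANTS) -> int:
    """Total number of scan bins N covering the desired span.

    N = 96 * ceil(2 (R2~ - R1~) / (5.8594 c)): the two-way travel time of the
    span, rounded up to whole stack segments.
    """
    span = desired.r2_desired - desired.r1_desired
    n_segments = math.ceil(2.0 * span / (constants.segment_duration_ns * constants.c))
    return constants.bins_per_segment * n_segments


def compute_t1(r1_desired: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Fast-time start instant T1 (ns) for the desired near range.

    The requested instant 2 R1~/c + 10 ns is floored to the fine-bin grid:
    T1 = floor(b * floor(1000/b * (2 R1~/c + 10))) / 1000 with b the fine-bin
    duration in ps.
    """
    if r1_desired < 0:
        raise TimingError("r1_desired must be non-negative")
    b = constants.bin_duration_ps
    requested_ns = 2.0 * r1_desired / constants.c + constants.min_fast_time_ns
    return math.floor(b * math.floor(1000.0 / b * requested_ns)) / 1000.0


def compute_t2(n_bins: int, t1: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Fast-time end instant T2 (ns) after N bins starting at T1.

    T2 = floor(b * ceil(32 N + 1000 T1 / b)) / 1000; each scan bin advances
    the fine sampler by 32 quanta.
    """
    if n_bins <= 0 or n_bins % constants.bins_per_segment:
        raise TimingError("n_bins must be a positive multiple of 96")
    if t1 < constants.min_fast_time_ns:
        raise TimingError("t1 must be >= 10 ns")
    b = constants.bin_duration_ps
    return math.floor(b * math.ceil(32.0 * n_bins + 1000.0 * t1 / b)) / 1000.0


def compute_actual_range(
    t1: float, t2: float, constants: PhysicalConstants = CONSTANTS
) -> tuple[float, float]:
    """Actual range window [R1, R2] = c/2 (T - 10 ns) for T in {T1, T2}."""
    if not t2 > t1 >= constants.min_fast_time_ns:
        raise TimingError("need t2 > t1 >= 10 ns")
    offset = constants.min_fast_time_ns
    return (
        constants.c / 2.0 * (t1 - offset),
        constants.c / 2.0 * (t2 - offset),
    )


def _round_half_away(x: float) -> float:
    # Table-derived inputs never land on .5; fixed to half-away-from-zero.
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def compute_scan_duration(
    pii: int, t1: float, t2: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Slow-time duration ts (us) of one full scan.

    ts = 0.792 * 2**PII * Round((T2 - T1) / 5.8594): one 0.792-us slot per
    pulse repetition per stack segment, 2**PII integrated pulses.
    """
    if not PII_MIN <= pii <= PII_MAX:
        raise TimingError(f"PII must lie in [{PII_MIN}, {PII_MAX}], got {pii}")
    n_segments = _round_half_away((t2 - t1) / constants.segment_duration_ns)
    return constants.base_scan_slot_us * 2**pii * n_segments


def compute_idle_time(ts: float, fs: float) -> float:
    """Idle interval ti (us) between scans so that ts + ti = 1e6/fs."""
    period = 1e6 / fs
    if ts >= period:
        raise TimingError(
            f"scan duration {ts} us exceeds the sampling period {period} us"
        )
    return period - ts


def snr_gain_db(num_integrated_scans: int) -> float:
    """SNR improvement (dB) from rake integration of 2**k pulses.

    64 integrated pulses give 18 dB; each doubling adds 3 dB up to 32768
    (45 dB).
    """
    n = num_integrated_scans
    if n < 2**PII_MIN or n > 2**PII_MAX or n & (n - 1):
        raise TimingError(
            f"integrated scans must be a power of two in [64, 32768], got {n}"
        )
    return 18.0 + 3.0 * math.log2(n / 64)


def derive_timing(
    desired: DesiredRange,
    pii: int = 12,
    fs: float = 50.0,
    constants: PhysicalConstants = CONSTANTS,
) -> TimingPlan:
    """Derive the full acquisition plan for a desired range window."""
    n_bins = compute_scan_bins(desired, constants)
    t1 = compute_t1(desired.r1_desired, constants)
    t2 = compute_t2(n_bins, t1, constants)
    r1, r2 = compute_actual_range(t1, t2, constants)
    ts = compute_scan_duration(pii, t1, t2, constants)
    ti = compute_idle_time(ts, fs)
    return TimingPlan(
        n_bins=n_bins, t1=t1, t2=t2, r1=r1, r2=r2,
        ts=ts, ti=ti, pii=pii, fs=fs, constants=constants,
    )
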