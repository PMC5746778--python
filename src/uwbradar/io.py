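"""Scan container and tabular I/O.

A :class:`ScanMatrix` is the canonical in-memory object flowing through the
pipeline: a real-valued (n_scans x n_bins) array of radar samples, slow time
along axis 0 at ``timing.fs`` Hz and fast time along axis 1 on the grid
defined by the :class:`~uwbradar.mrm_timing.TimingPlan`.  On disk it is a
chunked HDF5 file (``samples`` dataset) with the timing plan and provenance
stored as a JSON attribute, plus an optional human-readable JSON sidecar.
Ground truth and signature tables travel as plain CSV via pandas.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .mrm_timing import CONSTANTS, PhysicalConstants, TimingPlan

__all__ = [
    "ScanMatrix",
    "ContainerError",
    "read_scan_container",
    "write_scan_container",
    "read_ground_truth",
    "write_ground_truth",
]

GROUND_TRUTH_COLUMNS = [
    "scan_index",
    "time_s",
    "range_m",
    "hr_bpm",
    "rr_brpm",
    "activity",
    "people_count",
]


class ContainerError(ValueError):
    """Malformed or inconsistent scan container."""


@dataclass
class ScanMatrix:
    """Radar scans: ``samples[i, j]`` = scan i, fast-time bin j."""

    samples: np.ndarray
    timing: TimingPlan
    start_time: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ContainerError("samples must be 2-D (n_scans x n_bins)")
        if self.samples.shape[1] != self.timing.n_bins:
            raise ContainerError(
                f"samples have {self.samples.shape[1]} bins, timing plan "
                f"expects {self.timing.n_bins}"
            )

    @property
    def n_scans(self) -> int:
        return self.samples.shape[0]

    @property
    def n_bins(self) -> int:
        return self.samples.shape[1]

    def slow_time_axis(self) -> np.ndarray:
        """Acquisition time (s) of each scan."""
        return self.start_time + np.arange(self.n_scans) / self.timing.fs

    def range_axis(self) -> np.ndarray:
        return self.timing.range_axis()

    def with_samples(self, samples: np.ndarray) -> "ScanMatrix":
        """Copy of this container holding different samples, same metadata."""
        return ScanMatrix(samples, self.timing, self.start_time, self.seed)


def _timing_to_dict(plan: TimingPlan) -> dict:
    d = dataclasses.asdict(plan)
    d["constants"] = dataclasses.asdict(plan.constants)
    return d


def _timing_from_dict(d: dict) -> TimingPlan:
    d = dict(d)
    constants = PhysicalConstants(**d.pop("constants", {})) if "constants" in d else CONSTANTS
    return TimingPlan(constants=constants, **d)


def write_scan_container(matrix: ScanMatrix, path: str | Path, sidecar: bool = True) -> None:
    """Write a scan matrix to a chunked HDF5 container (+ JSON sidecar)."""
    path = Path(path)
    meta = {
        "format": "uwbradar-scan",
        "version": 1,
        "timing": _timing_to_dict(matrix.timing),
        "start_time": matrix.start_time,
        "seed": matrix.seed,
    }
    with h5py.File(path, "w") as f:
        chunk_rows = min(matrix.n_scans, 256) or 1
        f.create_dataset(
            "samples",
            data=matrix.samples,
            chunks=(chunk_rows, matrix.n_bins),
            compression="gzip",
            compression_opts=4,
        )
        f.attrs["metadata"] = json.dumps(meta)
    if sidecar:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_scan_container(path: str | Path) -> ScanMatrix:
    """Read a scan matrix written by :func:`write_scan_container`."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if "samples" not in f or "metadata" not in f.attrs:
                raise ContainerError(f"{path} is not a uwbradar scan container")
            meta = json.loads(f.attrs["metadata"])
            samples = f["samples"][()]
    except OSError as exc:  # truncated / not HDF5
        raise ContainerError(f"cannot read scan container {path}: {exc}") from exc
    if meta.get("format") != "uwbradar-scan":
        raise ContainerError(f"{path}: unrecognized container format")
    timing = _timing_from_dict(meta["timing"])
    if samples.shape[1] != timing.n_bins:
        raise ContainerError(
            f"{path}: samples have {samples.shape[1]} bins but timing plan "
            f"declares {timing.n_bins}"
        )
    return ScanMatrix(samples, timing, meta.get("start_time", 0.0), meta.get("seed"))


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in GROUND_TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ContainerError(f"ground-truth table missing columns {missing}")
    truth.to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path)
    missing = [c for c in GROUND_TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ContainerError(f"ground-truth table missing columns {missing}")
    return truth
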