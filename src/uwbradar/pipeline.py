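"""End-to-end processing: simulate -> pre-process -> movements -> vitals
(-> fall detection), mirroring the three-stage smart-sensor architecture."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import falldetect, micromotion, preprocess, vitals
from .config import RunConfig, config_hash
from .doppler import SpectrogramSpec, doppler_spectrogram
from .io import ScanMatrix, write_ground_truth, write_scan_container
from .mrm_timing import DesiredRange, derive_timing
from .simulate import Actor, Interference, SceneScript, render_scans

__all__ = ["PipelineError", "run_pipeline", "signatures_to_frame", "process_scan"]

log = logging.getLogger("uwbradar")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def signatures_to_frame(sigs: list[micromotion.MicroMotionSignature]) -> pd.DataFrame:
    """Signature sequence as a flat table (window_start, d, amplitude,
    per-Doppler-bin profile columns)."""
    if not sigs:
        return pd.DataFrame()
    n = sigs[0].profile.size
    rows = {
        "window_start": [s.window_start for s in sigs],
        "distance_m": [s.distance for s in sigs],
        "amplitude": [s.amplitude for s in sigs],
    }
    for j in range(n):
        rows[f"profile_{j}"] = [s.profile[j] for s in sigs]
    return pd.DataFrame(rows)


def process_scan(scan: ScanMatrix, config: RunConfig):
    """Shared processing chain: filters -> spectrogram -> signatures."""
    if config.filters.fasttime_enabled:
        scan = preprocess.apply_fasttime_filter(scan)
    cspec = preprocess.ClutterRemovalSpec(
        n_components=config.filters.clutter_n_components,
        energy_fraction=config.filters.clutter_energy_fraction,
    )
    clutter_free = preprocess.svd_clutter_removal(scan, cspec)
    spec = SpectrogramSpec(
        n_dtft=config.spectrogram.n_dtft,
        overlap=config.spectrogram.overlap,
        fr=clutter_free.timing.fs,
        window=config.spectrogram.window,
    )
    spectrogram = doppler_spectrogram(clutter_free, spec)
    sigs = micromotion.extract_signature(
        spectrogram,
        micromotion.SignatureSpec(
            n_s=config.signature.n_s, stride_frames=config.signature.stride_frames
        ),
    )
    return clutter_free, spectrogram, sigs


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full chain on the configured synthetic scene.

    Writes the raw scan container, ground truth, signature and vitals CSVs
    and (when the detector is enabled) a fall-event JSON into the output
    directory; every artifact carries the config hash.  Deterministic under
    a fixed config seed.  Returns the artifact paths.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = config_hash(config)

    timing = _stage("timing")(derive_timing)(
        DesiredRange(config.timing.r1_desired, config.timing.r2_desired),
        pii=config.timing.pii,
        fs=config.timing.fs,
    )

    @_stage("simulate")
    def _simulate():
        interference = (
            Interference(**config.scene.interference.model_dump())
            if config.scene.interference
            else None
        )
        scene = SceneScript(
            actors=tuple(Actor(**a.model_dump()) for a in config.scene.actors),
            duration=config.scene.duration,
            noise_sigma=config.scene.noise_sigma,
            interference=interference,
            seed=config.seed,
        )
        return render_scans(scene, timing)

    scan, truth = _simulate()
    scan_path = out / f"scans_{stamp}.h5"
    write_scan_container(scan, scan_path)
    truth_path = out / f"ground_truth_{stamp}.csv"
    write_ground_truth(truth, truth_path)

    clutter_free, _, sigs = _stage("preprocess+movements")(process_scan)(scan, config)
    sig_path = out / f"signatures_{stamp}.csv"
    signatures_to_frame(sigs).to_csv(sig_path, index=False)

    @_stage("vitals")
    def _vitals():
        filtered = vitals.apply_slowtime_filter(clutter_free)
        rows = []
        t_end = clutter_free.n_scans / timing.fs
        start = 0.0
        while start + config.vitals.window_s <= t_end + 1e-9:
            window = (start, start + config.vitals.window_s)
            in_window = [
                s for s in sigs if window[0] <= s.window_start < window[1]
            ]
            try:
                region = micromotion.movement_region(
                    in_window or sigs, config.signature.movement_threshold
                )
            except micromotion.NoMovementError:
                start += config.vitals.stride_s
                continue
            est = vitals.estimate_rates(
                filtered,
                region,
                window=window,
                max_bins=config.vitals.max_bins,
                band_split_hz=config.vitals.band_split_hz,
            )
            rows.append(
                {
                    "window_start": window[0],
                    "hr_bpm": est.hr,
                    "rr_brpm": est.rr,
                    "hr_missing": est.flags["hr_missing"],
                    "rr_missing": est.flags["rr_missing"],
                }
            )
            start += config.vitals.stride_s
        return pd.DataFrame(rows)

    vitals_path = out / f"vitals_{stamp}.csv"
    _vitals().to_csv(vitals_path, index=False)

    artifacts = {
        "config_hash": stamp,
        "scans": str(scan_path),
        "ground_truth": str(truth_path),
        "signatures": str(sig_path),
        "vitals": str(vitals_path),
    }

    if config.detector.enabled:

        @_stage("falldetect")
        def _falls():
            fspec = falldetect.FeatureSpec(
                window_s=config.detector.window_s, stride_s=config.detector.stride_s
            )
            windows = falldetect.build_features(sigs, fspec)
            if config.detector.model_path:
                import joblib

                model = joblib.load(config.detector.model_path)
            else:
                train_set = [
                    w for w in windows if w.start < config.detector.train_seconds
                ]
                model = falldetect.train(
                    train_set,
                    mode=config.detector.mode,
                    nu=config.detector.nu,
                    gamma=config.detector.gamma,
                    threshold=config.detector.threshold,
                    training_minutes=config.detector.train_seconds / 60.0,
                    seed=config.seed,
                )
            labels, scores = falldetect.detect(model, windows)
            events = falldetect.merge_events(labels)
            return {
                "config_hash": stamp,
                "n_windows": len(windows),
                "events": [
                    {
                        "start_s": windows[i].start,
                        "end_s": windows[j].start + config.detector.window_s,
                        "peak_score": float(np.max(scores[i : j + 1])),
                    }
                    for i, j in events
                ],
            }

        events_path = out / f"fall_events_{stamp}.json"
        events_path.write_text(json.dumps(_falls(), indent=2))
        artifacts["fall_events"] = str(events_path)

    (out / f"run_{stamp}.json").write_text(
        json.dumps({"config": config.model_dump(), "artifacts": artifacts}, indent=2)
    )
    return artifacts
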