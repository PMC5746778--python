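"""Schema-validated run configuration (YAML), with strict unknown-key
rejection and a single global seed that fans out to every stochastic stage."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TimingConfig(_Strict):
    r1_desired: float = 0.5
    r2_desired: float = 5.5
    pii: int = 12
    fs: float = 50.0


class ActorConfig(_Strict):
    kind: str = "stationary_subject"
    base_range: float = 2.0
    rr: float = 15.0
    hr: float = 72.0
    resp_amplitude: float = 0.006
    heart_amplitude: float = 0.0003
    reflectivity: float = 1.0
    activity: str | None = None
    walk_speed: float = 0.5
    walk_span: float = 1.5
    stride_rate: float = 1.0
    limb_amplitude: float = 0.2
    limb_reflectivity: float = 0.3
    fall_time: float = 10.0
    fall_duration: float = 1.0
    fall_range_shift: float = 1.3
    fall_rcs_gain: float = 4.0
    precordial_offset: float = 0.12
    precordial_resp_fraction: float = 0.1
    precordial_reflectivity: float = 0.6
    cardiac_harmonic_ratio: float = 0.2


class InterferenceConfig(_Strict):
    frequency_ghz: float
    amplitude: float


class SceneConfig(_Strict):
    actors: list[ActorConfig] = Field(default_factory=list)
    duration: float = 60.0
    noise_sigma: float = 0.2
    interference: InterferenceConfig | None = None


class FilterConfig(_Strict):
    fasttime_enabled: bool = True
    clutter_n_components: int | None = None
    clutter_energy_fraction: float | None = None


class SpectrogramConfig(_Strict):
    n_dtft: int = 16
    overlap: float = 0.5
    window: str = "rectangular"


class SignatureConfig(_Strict):
    n_s: int = 9
    stride_frames: int = 1
    movement_threshold: float = 0.0


class VitalsConfig(_Strict):
    window_s: float = 30.0
    stride_s: float = 15.0
    max_bins: int = 24
    band_split_hz: float = 0.7


class DetectorConfig(_Strict):
    enabled: bool = False
    mode: str = "unsupervised"
    nu: float = 0.05
    gamma: float | str = "scale"
    threshold: float = 0.0
    window_s: float = 4.0
    stride_s: float = 1.0
    train_seconds: float = 30.0  # leading ADL span used by the demo pipeline
    model_path: str | None = None  # pre-trained model overrides train_seconds


class RunConfig(_Strict):
    timing: TimingConfig = Field(default_factory=TimingConfig)
    scene: SceneConfig = Field(default_factory=SceneConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    spectrogram: SpectrogramConfig = Field(default_factory=SpectrogramConfig)
    signature: SignatureConfig = Field(default_factory=SignatureConfig)
    vitals: VitalsConfig = Field(default_factory=VitalsConfig)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    seed: int = 0
    output_dir: str = "out"


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash stamped onto every pipeline artifact."""
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
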