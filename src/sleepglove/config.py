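"""Run configuration.

Every parameter the recording device or the analysis leaves open —
detector prominences, DAP thresholds, desaturation magnitude, fusion noise
levels, the movement threshold — is surfaced here so a run is fully
described by one YAML file with sections ``codec``, ``heart``,
``respiration``, ``sdb``, ``stages`` and ``synth``.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class CodecConfig(BaseModel):
    device_id: str = "UPNEA-0"
    shuffle_blocks_on_disk: bool = False


class HeartConfig(BaseModel):
    """Pulse detection and arrhythmia thresholds.

    ``brady_ibi_ms``/``tachy_ibi_ms`` are equivalent to 50 and 120 bpm;
    ``min_prominence`` applies to the z-scored signal.
    """

    brady_ibi_ms: float = 1200.0
    tachy_ibi_ms: float = 500.0
    af_pvc_delta_ms: float = 50.0
    min_prominence: float = 0.8
    refractory_s: float = 0.3
    ectopic_deviation: float = 0.3
    ectopic_kernel: int = 5
    episode_rule: Literal["mean", "any"] = "mean"
    deviation_rule: Literal["mean", "consecutive"] = "mean"

    @model_validator(mode="after")
    def _ordered(self) -> "HeartConfig":
        if not self.brady_ibi_ms > self.tachy_ibi_ms > 0:
            raise ValueError("brady threshold must exceed tachy threshold")
        if self.af_pvc_delta_ms <= 0:
            raise ValueError("af_pvc_delta_ms must be positive")
        return self


class RespirationConfig(BaseModel):
    """Breathing-rate estimation parameters.

    The respiratory search band is [4, 60] breaths/min; window estimates
    are fused by a random-walk Kalman smoother whose measurement variance
    scales as 1/quality (quality = spectral peak concentration in band).
    """

    grid_fs: float = 4.0
    band_breaths_min: tuple[float, float] = (4.0, 60.0)
    window_len_s: Literal[32, 64] = 64
    hop_s: float | None = None          # default: half the window
    quality_floor: float = 0.2
    process_sd_bpm: float = 0.5
    measurement_sd_bpm: float = 1.0     # at quality 1
    riiv_cutoff_hz: float = 0.5


class SdbConfig(BaseModel):
    """Sleep-disordered-breathing detection and classification."""

    envelope_baseline_s: float = 150.0
    depth_threshold: float = 0.3
    min_dur_s: float = 10.0
    merge_gap_s: float = 5.0
    desat_drop: float = 3.0
    desat_baseline_s: float = 120.0
    coupling_window_s: float = 20.0
    coupling_mode: Literal["left", "centered"] = "left"
    feature_window_s: float = 65.0
    kernel_scale: float = 0.56
    n_selected_features: int = 5
    cv_folds: int = 10
    svm_c: float = 1.0


class StagesConfig(BaseModel):
    """Actigraphy staging: movement threshold in device-units/s."""

    delta_s: float = 0.02
    movement_threshold: float = 15.0
    sd_ddof: Literal[0, 1] = 1


class RunConfig(BaseModel):
    codec: CodecConfig = Field(default_factory=CodecConfig)
    heart: HeartConfig = Field(default_factory=HeartConfig)
    respiration: RespirationConfig = Field(default_factory=RespirationConfig)
    sdb: SdbConfig = Field(default_factory=SdbConfig)
    stages: StagesConfig = Field(default_factory=StagesConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
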