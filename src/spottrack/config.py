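"""YAML configuration for the command-line pipeline.

A config file holds the camera model, detection and sifting parameters, and
the channel interleaving pattern; any value may be omitted and falls back to
the documented default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .camera_io import CameraModel


@dataclass
class PipelineConfig:
    camera: CameraModel = field(default_factory=CameraModel)
    pixel_size: float = 53.0  # nm
    frame_interval: float = 10.0  # ms
    psf_sigma_px: float = 1.4
    permissive_snr: float = 0.2
    snr_threshold: float = 0.4
    min_consecutive: int = 3
    channel_pattern: tuple[str, ...] = ("0",)
    kernel_width: float = 0.3  # molecules, periodicity analysis
    n_fit_lags: int = 4


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cam = CameraModel(**raw.pop("camera", {}))
    if "channel_pattern" in raw:
        raw["channel_pattern"] = tuple(raw["channel_pattern"])
    return PipelineConfig(camera=cam, **raw)
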