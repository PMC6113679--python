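"""Workflow configuration from a single YAML key-value file.

Recognized keys (all optional; defaults are the curated-database protocol):

    spectral_range:      [1250, 3600]      # cm^-1
    atr_artifact_range:  [1970, 2475]      # cm^-1
    co2_range:           [2200, 2420]      # cm^-1
    thresholds:          {raw: 0.6, derivative: 0.6}
    closing_radius:      1                 # pixels
    size_classes:        [11, 20, 30, ...] # um, lower class edges
    color_map:           {4: [166, 86, 40], ...}  # cluster -> RGB
    rubberband:          {iterations: 10, points: 64}
    derivative:          {window: 9, polyorder: 2}
    snr_min:             10
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .matching import MatchConfig
from .preprocess import PreprocessConfig

__all__ = ["WorkflowConfig", "load_config"]


@dataclass(frozen=True)
class WorkflowConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    closing_radius: int = 1
    size_classes: np.ndarray | None = None
    color_map: dict[int, tuple[int, int, int]] | None = None


def load_config(path: str | Path | None) -> WorkflowConfig:
    """Parse a YAML config file; a missing path yields all defaults."""
    if path is None:
        return WorkflowConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    pp_kwargs: dict = {}
    if "spectral_range" in raw:
        pp_kwargs["spectral_range"] = tuple(map(float, raw["spectral_range"]))
    if "atr_artifact_range" in raw:
        pp_kwargs["atr_artifact_range"] = tuple(map(float, raw["atr_artifact_range"]))
    if "co2_range" in raw:
        pp_kwargs["co2_range"] = tuple(map(float, raw["co2_range"]))
    if "rubberband" in raw:
        pp_kwargs["rubberband_iterations"] = int(raw["rubberband"].get("iterations", 10))
        pp_kwargs["rubberband_points"] = int(raw["rubberband"].get("points", 64))
    if "derivative" in raw:
        pp_kwargs["derivative_window"] = int(raw["derivative"].get("window", 9))
        pp_kwargs["derivative_polyorder"] = int(raw["derivative"].get("polyorder", 2))
    if "snr_min" in raw:
        pp_kwargs["snr_min"] = float(raw["snr_min"])
    mc_kwargs: dict = {}
    if "thresholds" in raw:
        mc_kwargs["threshold_raw"] = float(raw["thresholds"].get("raw", 0.6))
        mc_kwargs["threshold_derivative"] = float(raw["thresholds"].get("derivative", 0.6))
    if "spectral_range" in raw:
        mc_kwargs["spectral_range"] = tuple(map(float, raw["spectral_range"]))
    return WorkflowConfig(
        preprocess=PreprocessConfig(**pp_kwargs),
        match=MatchConfig(**mc_kwargs),
        closing_radius=int(raw.get("closing_radius", 1)),
        size_classes=(
            np.asarray(raw["size_classes"], dtype=float)
            if "size_classes" in raw
            else None
        ),
        color_map=(
            {int(k): tuple(v) for k, v in raw["color_map"].items()}
            if "color_map" in raw
            else None
        ),
    )
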