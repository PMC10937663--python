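"""Schema-validated run configuration.

A YAML file drives the end-to-end pipeline; every key is validated on load
and unknown keys are rejected with their location, so typos fail fast
instead of silently using defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    shape: Tuple[int, int, int] = (128, 64, 384)
    axial_pitch_um: float = 5.46875   # 500 um of tissue == 128 depth pixels
    lateral_pitch_um: Tuple[float, float] = (10.0, 10.0)
    refractive_index: float = 1.4
    mu_t: float = 4.0
    source_level_db: float = 45.0
    surface_offset_px: int = 20
    surface_tilt_um: Tuple[float, float] = (0.0, 0.0)
    speckle_contrast: float = 1.0
    n_lymphatic: int = 5
    n_vein: int = 3
    vessel_deficit_db: float = 20.0
    layer_thickness_um: Optional[float] = None
    layer_deficit_db: float = 10.0


class CannyConfig(_Strict):
    sigma: float = 2.0
    low: float = 0.1
    high: float = 0.3
    median_width: int = 15


class FitConfig(_Strict):
    guard_px: int = 5
    noise_margin_db: float = 3.0
    min_window_px: int = 20


class ConventionalSection(_Strict):
    theta_db: Optional[float] = None
    theta_rel_db: float = 10.0
    crop_um: float = 500.0
    mu_cal: float = 0.0
    speckle_smooth_px: int = 3
    canny: CannyConfig = Field(default_factory=CannyConfig)
    fit: FitConfig = Field(default_factory=FitConfig)


class UNetSection(_Strict):
    widths: Tuple[int, int, int, int] = (32, 64, 128, 256)
    seed: int = 0


class TrainSection(_Strict):
    lr: float = 1e-4
    epochs: int = 150
    batch_size: int = 4
    split: Tuple[float, float, float] = (0.5, 0.25, 0.25)
    stop_train_loss: Optional[float] = None
    stop_train_iou: Optional[float] = None


class ProjectionSection(_Strict):
    # per-figure presets: full superficial window, or artifact-excluding
    window_um: Tuple[float, float] = (0.0, 300.0)
    weighted: bool = False


class RunConfig(_Strict):
    """Top-level configuration for the end-to-end pipeline."""

    schema_version: int = 1
    seed: int = 0
    out_dir: str = "octl_run"
    calibration: Optional[str] = None      # path; None = simulate
    volume: Optional[str] = None           # path; None = simulate
    simulate: bool = True
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    conventional: ConventionalSection = Field(default_factory=ConventionalSection)
    unet: UNetSection = Field(default_factory=UNetSection)
    train: TrainSection = Field(default_factory=TrainSection)
    projection: ProjectionSection = Field(default_factory=ProjectionSection)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
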