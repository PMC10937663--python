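"""Core volumetric containers for OCT lymphangiography processing.

The substrate of every processing stage is a 3-D log-intensity scan
(:class:`OCTVolume`), stored as a ``[x, y, z]`` array in dB with axial and
lateral pixel pitches.  The axial axis is indexed from the shallowest sample
(``z = 0``) downward, and axial distances are expressed in optical path
length; dividing by the tissue refractive index converts them to physical
(tissue) length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["OCTVolume", "VesselMask"]


@dataclass
class OCTVolume:
    """A 3-D logarithmic OCT scan.

    Parameters
    ----------
    data
        Log intensity in dB, shaped ``(nx, ny, nz)``.  ``y`` indexes
        B-scans; a single B-scan is the ``(nx, nz)`` slice at fixed ``y``.
    axial_pitch_um
        Axial sampling pitch in micrometres of *optical path* per pixel.
    lateral_pitch_um
        Lateral sampling pitch ``(x, y)`` in micrometres per pixel.
    refractive_index
        Group refractive index used to convert optical to physical depth.
    noise_normalized
        True once the noise floor has been subtracted so that a fully
        attenuated region averages 0 dB.
    """

    data: np.ndarray
    axial_pitch_um: float
    lateral_pitch_um: tuple[float, float] = (13.0, 13.0)
    refractive_index: float = 1.4
    noise_normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        if self.axial_pitch_um <= 0 or min(self.lateral_pitch_um) <= 0:
            raise ValueError("pixel pitches must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("OCT volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def nz(self) -> int:
        return self.data.shape[2]

    @property
    def physical_pitch_um(self) -> float:
        """Axial pitch in micrometres of tissue per pixel."""
        return self.axial_pitch_um / self.refractive_index

    def depth_axis_mm(self, physical: bool = True) -> np.ndarray:
        """Depth of each axial sample in millimetres (physical by default)."""
        pitch = self.physical_pitch_um if physical else self.axial_pitch_um
        return np.arange(self.nz) * pitch * 1e-3

    def with_data(self, data: np.ndarray, **updates) -> "OCTVolume":
        """Copy of this volume with new voxel data and optional field updates."""
        return replace(self, data=np.asarray(data, dtype=np.float32), **updates)


@dataclass
class VesselMask:
    """A binary vessel segmentation on the grid of its source volume.

    ``frame`` records whether depth index 0 is the native shallowest sample
    (``"native"``) or the flattened tissue surface (``"flattened"``);
    ``provenance`` records which segmentation method produced the mask.
    """

    data: np.ndarray
    frame: str = "native"
    provenance: str = "conventional"
    crop_um: Optional[float] = None
    physical_pitch_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got shape {self.data.shape}")
        if self.frame not in ("native", "flattened"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.provenance not in ("conventional", "dl", "ground_truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape
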