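"""Segmentation agreement metrics and en face vessel projections.

Agreement between two binary segmentations is quantified per B-scan by the
Intersection over Union (IOU), summarized over a volume as mean +/- sample
standard deviation.  Vessel abundance is reported as area density (fraction
of vessel pixels in a 2-D en face projection) and volume density (fraction
of vessel voxels in a 3-D depth window).  Projections collapse a depth
window of a surface-flattened mask to a top-down image: binary (logical
any) or weighted by the reversed OCT signal, which makes the most
transparent (lowest-signal) vessels brightest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import OCTVolume, VesselMask

__all__ = [
    "MetricsReport",
    "Projection",
    "iou",
    "iou_summary",
    "project",
    "weighted_project",
    "area_density",
    "volume_density",
]


@dataclass
class MetricsReport:
    """Per-B-scan IOU list with summary statistics and densities."""

    per_bscan_iou: list[float]
    mean_iou: float
    sd_iou: float
    area_density_pct: float | None = None
    volume_density_pct: float | None = None
    window_um: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {
            "mean_iou": self.mean_iou,
            "sd_iou": self.sd_iou,
            "n_bscans": len(self.per_bscan_iou),
            "area_density_pct": self.area_density_pct,
            "volume_density_pct": self.volume_density_pct,
            "window_um": self.window_um,
            "per_bscan_iou": self.per_bscan_iou,
        }


@dataclass
class Projection:
    """A 2-D en face image over a depth window."""

    image: np.ndarray
    kind: str                      # "binary" | "weighted"
    window_um: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "weighted"):
            raise ValueError(f"unknown projection kind {self.kind!r}")


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over Union of two binary masks.

    Two empty masks agree perfectly and score 1 by convention.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def iou_summary(vol_a: VesselMask, vol_b: VesselMask) -> MetricsReport:
    """Per-B-scan IOU between two mask volumes, with mean and sample SD."""
    if vol_a.shape != vol_b.shape:
        raise ValueError("mask volumes must share a grid")
    ny = vol_a.shape[1]
    values = [iou(vol_a.data[:, y, :], vol_b.data[:, y, :]) for y in range(ny)]
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return MetricsReport(
        per_bscan_iou=[float(v) for v in values],
        mean_iou=float(arr.mean()),
        sd_iou=sd,
    )


def _window_slice(
    nz: int, pitch_um: float, window_um: tuple[float, float]
) -> slice:
    z0_um, z1_um = window_um
    if z1_um <= z0_um:
        raise ValueError("depth window must have positive extent")
    z0 = int(round(z0_um / pitch_um))
    z1 = int(round(z1_um / pitch_um))
    if z0 >= nz:
        raise ValueError(
            f"window {window_um} um lies outside the {nz}-pixel crop"
        )
    return slice(max(z0, 0), min(z1, nz))


def project(
    mask: VesselMask, window_um: tuple[float, float] | None = None
) -> Projection:
    """Binary en face projection: pixel true iff any vessel voxel in window."""
    if mask.frame != "flattened":
        raise ValueError("projection requires a surface-flattened mask")
    nz = mask.shape[2]
    pitch = mask.physical_pitch_um
    if window_um is None:
        window_um = (0.0, nz * pitch)
    sl = _window_slice(nz, pitch, window_um)
    img = mask.data[:, :, sl].any(axis=2)
    return Projection(image=img, kind="binary", window_um=tuple(window_um))


def weighted_project(
    mask: VesselMask,
    vol: OCTVolume,
    window_um: tuple[float, float] | None = None,
    vmax: float | None = None,
) -> Projection:
    """En face projection weighted by the reversed OCT signal.

    The per-voxel weight is ``(vmax - dB)/vmax`` clipped to [0, 1] with
    ``vmax`` the volume's 99.9th percentile, so originally transparent
    (low-signal) vessel interiors project brightly.  Each pixel is the mean
    weight over the mask voxels in the window (0 where the column holds no
    vessel).
    """
    if mask.frame != "flattened":
        raise ValueError("projection requires a surface-flattened mask")
    if mask.shape != vol.shape:
        raise ValueError("mask and volume must share the flattened frame and grid")
    if vmax is None:
        vmax = float(np.percentile(vol.data, 99.9))
    nz = mask.shape[2]
    pitch = mask.physical_pitch_um or vol.physical_pitch_um
    if window_um is None:
        window_um = (0.0, nz * pitch)
    sl = _window_slice(nz, pitch, window_um)
    w = np.clip((vmax - vol.data[:, :, sl]) / vmax, 0.0, 1.0)
    m = mask.data[:, :, sl]
    count = m.sum(axis=2)
    total = (w * m).sum(axis=2)
    img = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return Projection(image=img, kind="weighted", window_um=tuple(window_um))


def area_density(p: Projection) -> float:
    """Vessel area density: percentage of true pixels in a binary projection."""
    if p.kind != "binary":
        raise ValueError("area density is defined on binary projections")
    return float(100.0 * p.image.mean())


def volume_density(
    mask: VesselMask, window_um: tuple[float, float] | None = None
) -> float:
    """Vessel volume density: percentage of vessel voxels in a depth window."""
    if mask.frame != "flattened":
        raise ValueError("volume density requires a surface-flattened mask")
    nz = mask.shape[2]
    pitch = mask.physical_pitch_um
    if window_um is None:
        window_um = (0.0, nz * pitch)
    sl = _window_slice(nz, pitch, window_um)
    sub = mask.data[:, :, sl]
    if sub.size == 0:
        raise ValueError("empty depth window")
    return float(100.0 * sub.mean())
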