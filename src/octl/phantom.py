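"""Synthetic OCT phantoms with ground-truth vessel geometry.

Real scans of ocular tissue are not redistributable, so every stage of the
pipeline is exercised on simulated volumes.  The renderer follows the
single-scattering picture of OCT: the expected backscattered intensity at
depth ``z`` below the tissue surface is

    I(z) = I0 * H(z) * exp(-2 * mu * z)

where ``mu`` (mm^-1) is the tissue attenuation coefficient, the factor 2
accounts for the round trip, and ``H(z)`` is the axial system response — a
Lorentzian-like confocal collection factor multiplied by an exponential
(linear-in-dB) spectrometer sensitivity roll-off.  Displayed values are
``10*log10(I)`` with the noise floor near 0 dB.

Optically transparent vessels (lymphatics, aqueous veins) backscatter far
less than the surrounding stroma; they are rendered as tubes whose interior
signal is lower by a configurable deficit in dB.  Lymphatic-like tubes have
irregular centerlines and uneven radii; vein-like tubes are straighter and
of regular calibre.  Speckle is modelled as multiplicative unit-mean
exponentially distributed intensity noise (fully developed speckle), and
the noise floor as additive intensity.

Ground truth is geometric: a voxel belongs to a vessel iff its centre lies
within the local tube radius of the centerline, independent of the rendered
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .preprocess import DB_PER_NEPER, RawSpectra
from .volume import OCTVolume

__all__ = [
    "Vessel",
    "SuperficialLayer",
    "PhantomSpec",
    "GroundTruth",
    "make_calibration_volume",
    "make_eye_phantom",
    "make_raw_spectra",
    "sample_vessels",
    "system_response_db",
]


@dataclass
class Vessel:
    """A tubular low-signal structure.

    ``centerline`` is an ``(n, 3)`` polyline in voxel coordinates
    ``(x, y, z)``; ``radius_um`` is either a scalar or one radius per
    vertex (linearly interpolated along segments); ``deficit_db`` is how
    far the interior signal sits below the surrounding tissue.
    """

    centerline: np.ndarray
    radius_um: float | np.ndarray
    kind: str = "lymphatic"
    deficit_db: float = 15.0

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[1] != 3:
            raise ValueError("centerline must be (n, 3) voxel coordinates")
        r = np.asarray(self.radius_um, dtype=float)
        if r.ndim == 0:
            r = np.full(len(self.centerline), float(r))
        if len(r) != len(self.centerline):
            raise ValueError("radius profile length must match centerline")
        if np.any(r <= 0):
            raise ValueError("vessel radii must be positive")
        self.radius_um = r
        if self.kind not in ("lymphatic", "vein"):
            raise ValueError(f"unknown vessel kind {self.kind!r}")
        if self.deficit_db <= 0:
            raise ValueError("vessel signal deficit must be > 0 dB")


@dataclass
class SuperficialLayer:
    """A uniformly darker layer just below the surface.

    Emulates a low-backscatter epithelium that breaks the depth homogeneity
    assumed by per-A-scan attenuation fitting, the source of superficial
    segmentation artifacts in the threshold-based method.
    """

    thickness_um: float
    deficit_db: float

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("layer thickness must be positive")
        if self.deficit_db <= 0:
            raise ValueError("layer signal deficit must be > 0 dB")


@dataclass
class PhantomSpec:
    """Full description of a synthetic scan; identical spec + seed gives
    bit-identical output arrays."""

    shape: tuple[int, int, int] = (256, 256, 512)
    axial_pitch_um: float = 3.52          # optical um / pixel (3.6 mm over 1024)
    lateral_pitch_um: tuple[float, float] = (2.93, 2.93)
    refractive_index: float = 1.4
    mu_t: float = 2.0                     # scleral stroma, mm^-1
    source_level_db: float = 45.0         # tissue surface level above noise floor
    surface_tilt_um: tuple[float, float] = (0.0, 0.0)   # optical um per lateral px
    surface_offset_px: int = 0
    noise_floor_db: float = 0.0
    speckle_contrast: float = 1.0
    vessels: Sequence[Vessel] = field(default_factory=tuple)
    superficial_layer: Optional[SuperficialLayer] = None
    confocal_focus_um: float = 300.0      # optical depth of focus
    confocal_rayleigh_um: float = 500.0   # apparent Rayleigh range
    rolloff_db_per_mm: float = 6.0        # sensitivity roll-off (optical mm)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 1:
            raise ValueError("phantom grid must be non-empty")
        if self.axial_pitch_um <= 0 or min(self.lateral_pitch_um) <= 0:
            raise ValueError("pixel pitches must be positive")
        if self.mu_t < 0:
            raise ValueError("attenuation coefficient must be >= 0")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle contrast must lie in [0, 1]")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def physical_pitch_um(self) -> float:
        return self.axial_pitch_um / self.refractive_index

    def surface_map(self) -> np.ndarray:
        """Integer surface depth index per A-scan (tilted plane)."""
        nx, ny, nz = self.shape
        tx, ty = self.surface_tilt_um
        xs = np.arange(nx)[:, None] * tx
        ys = np.arange(ny)[None, :] * ty
        surf = self.surface_offset_px + (xs + ys) / self.axial_pitch_um
        return np.clip(np.rint(surf).astype(int), 0, nz - 1)


@dataclass
class GroundTruth:
    """Geometric truth accompanying a rendered phantom."""

    mask: np.ndarray                 # (nx, ny, nz) bool, native frame
    surface: np.ndarray              # (nx, ny) int depth index
    attenuation: np.ndarray          # (nx, ny) true mu per A-scan, mm^-1


def system_response_db(spec: PhantomSpec, z_px: np.ndarray) -> np.ndarray:
    """Combined confocal x roll-off axial response in dB at depth pixels."""
    z_um = np.asarray(z_px, dtype=float) * spec.axial_pitch_um
    conf = 1.0 / (1.0 + ((z_um - spec.confocal_focus_um) / spec.confocal_rayleigh_um) ** 2)
    roll_db = -spec.rolloff_db_per_mm * z_um * 1e-3
    return 10.0 * np.log10(conf) + roll_db


def _voxelize(spec: PhantomSpec, vessels: Sequence[Vessel]) -> np.ndarray:
    """Geometric tube voxelization: centre-to-centerline distance <= radius.

    Distances are evaluated in physical micrometres so that the unequal
    axial/lateral pitches produce correctly shaped tubes.
    """
    nx, ny, nz = spec.shape
    px, py = spec.lateral_pitch_um
    pz = spec.physical_pitch_um
    scale = np.array([px, py, pz])
    mask = np.zeros(spec.shape, dtype=bool)
    for vessel in vessels:
        pts = vessel.centerline * scale[None, :]
        radii = np.asarray(vessel.radius_um, dtype=float)
        for i in range(max(1, len(pts) - 1)):
            p0 = pts[i]
            p1 = pts[min(i + 1, len(pts) - 1)]
            r0 = radii[i]
            r1 = radii[min(i + 1, len(radii) - 1)]
            rmax = max(r0, r1)
            lo = np.minimum(p0, p1) - rmax
            hi = np.maximum(p0, p1) + rmax
            i0 = np.maximum(np.floor(lo / scale).astype(int), 0)
            i1 = np.minimum(np.ceil(hi / scale).astype(int) + 1, [nx, ny, nz])
            if np.any(i0 >= i1):
                continue
            gx = np.arange(i0[0], i1[0]) * px
            gy = np.arange(i0[1], i1[1]) * py
            gz = np.arange(i0[2], i1[2]) * pz
            X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
            d = p1 - p0
            denom = float(d @ d)
            if denom == 0:
                t = np.zeros_like(X)
            else:
                t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / denom
                t = np.clip(t, 0.0, 1.0)
            cx = p0[0] + t * d[0]
            cy = p0[1] + t * d[1]
            cz = p0[2] + t * d[2]
            dist2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
            r_here = r0 + t * (r1 - r0)
            sub = dist2 <= r_here**2
            mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= sub
    return mask


def _render(
    spec: PhantomSpec,
    surface: np.ndarray,
    deficit_db_map: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render the dB volume given a surface map and optional deficit map."""
    nx, ny, nz = spec.shape
    z = np.arange(nz)
    depth_px = z[None, None, :] - surface[:, :, None]          # px below surface
    in_tissue = depth_px >= 0
    depth_mm = depth_px * spec.physical_pitch_um * 1e-3

    sig_db = (
        spec.source_level_db
        + system_response_db(spec, z)[None, None, :]
        - 2.0 * spec.mu_t * depth_mm * DB_PER_NEPER
    )
    if spec.superficial_layer is not None:
        thick_px = spec.superficial_layer.thickness_um / spec.physical_pitch_um
        layer = (depth_px >= 0) & (depth_px < thick_px)
        sig_db = sig_db - spec.superficial_layer.deficit_db * layer
    if deficit_db_map is not None:
        sig_db = sig_db - deficit_db_map

    sig_lin = np.where(in_tissue, 10.0 ** (sig_db / 10.0), 0.0)
    floor_lin = 10.0 ** (spec.noise_floor_db / 10.0)
    if spec.speckle_contrast > 0:
        c = spec.speckle_contrast
        speckle = rng.exponential(1.0, size=spec.shape)
        sig_lin = sig_lin * ((1.0 - c) + c * speckle)
        noise = floor_lin * ((1.0 - c) + c * rng.exponential(1.0, size=spec.shape))
    else:
        noise = floor_lin
    return (10.0 * np.log10(sig_lin + noise)).astype(np.float32)


def make_calibration_volume(spec: PhantomSpec) -> OCTVolume:
    """Render a homogeneous low-scattering calibration phantom.

    The phantom fills the whole depth range (surface at z = 0, no tilt), so
    the laterally averaged profile directly exposes the axial system
    response on top of the known attenuation slope.
    """
    if spec.vessels:
        raise ValueError("calibration phantom must be homogeneous: remove vessels")
    if spec.superficial_layer is not None:
        raise ValueError("calibration phantom must be homogeneous: remove layer")
    flat = replace(spec, surface_tilt_um=(0.0, 0.0), surface_offset_px=0)
    rng = np.random.default_rng(spec.seed)
    surface = np.zeros(spec.shape[:2], dtype=int)
    data = _render(flat, surface, None, rng)
    return OCTVolume(
        data=data,
        axial_pitch_um=spec.axial_pitch_um,
        lateral_pitch_um=spec.lateral_pitch_um,
        refractive_index=spec.refractive_index,
        noise_normalized=(spec.noise_floor_db == 0.0),
        meta={"seed": spec.seed, "mu_t": spec.mu_t, "calibration": True},
    )


def make_eye_phantom(spec: PhantomSpec) -> tuple[OCTVolume, GroundTruth]:
    """Render an eye-like phantom plus its geometric ground truth.

    Voxels above the tilted surface contain only the noise floor; vessels
    and the optional superficial layer darken the tissue signal by their
    configured deficits.  A vessel reaching the surface (or above it) is an
    error, reported with the offending vessel index.
    """
    surface = spec.surface_map()
    mask = np.zeros(spec.shape, dtype=bool)
    deficit = np.zeros(spec.shape, dtype=np.float32) if spec.vessels else None
    for idx, vessel in enumerate(spec.vessels):
        sub = _voxelize(spec, [vessel])
        zz = np.nonzero(sub)
        if zz[0].size and np.any(zz[2] <= surface[zz[0], zz[1]]):
            raise ValueError(f"vessel {idx} extends to or above the tissue surface")
        mask |= sub
        np.maximum(deficit, np.float32(vessel.deficit_db) * sub, out=deficit)
    rng = np.random.default_rng(spec.seed)
    data = _render(spec, surface, deficit, rng)
    vol = OCTVolume(
        data=data,
        axial_pitch_um=spec.axial_pitch_um,
        lateral_pitch_um=spec.lateral_pitch_um,
        refractive_index=spec.refractive_index,
        noise_normalized=(spec.noise_floor_db == 0.0),
        meta={"seed": spec.seed, "mu_t": spec.mu_t},
    )
    truth = GroundTruth(
        mask=mask,
        surface=surface,
        attenuation=np.full(spec.shape[:2], spec.mu_t),
    )
    return vol, truth


def make_raw_spectra(
    depth_reflectors: Sequence[tuple[float, float]],
    spec: PhantomSpec,
    n_spectral: int = 1024,
    center_wavelength_nm: float = 1300.0,
) -> RawSpectra:
    """Simulate raw spectral-domain interferograms for point reflectors.

    Each reflector ``(depth_um, amplitude)`` (depth in optical path length)
    contributes a cosine fringe ``2*a*cos(2*k*z)`` under the source
    envelope.  The wavelength grid is uniform in wavelength — hence
    non-uniform in wavenumber — with its span chosen so the reconstruction
    axial pitch equals ``spec.axial_pitch_um``.  The source spectrum is
    stored as the background.
    """
    pitch = spec.axial_pitch_um
    n = n_spectral
    max_depth = pitch * (n // 2 - 2)
    for z, _ in depth_reflectors:
        if not 0 <= z <= max_depth:
            raise ValueError(
                f"reflector depth {z} um outside unambiguous range [0, {max_depth:.0f}]"
            )
    kc = 2.0 * np.pi / (center_wavelength_nm * 1e-3)      # rad/um
    span = np.pi * (n - 1) / (n * pitch)
    k_lo, k_hi = kc - span / 2.0, kc + span / 2.0
    lam = np.linspace(2.0 * np.pi / k_hi, 2.0 * np.pi / k_lo, n) * 1e3  # nm
    k = 2.0 * np.pi / (lam * 1e-3)

    background = np.exp(-(((k - kc) / (span / 4.0)) ** 2))
    fringes = np.zeros(n)
    for z, a in depth_reflectors:
        fringes += 2.0 * a * np.cos(2.0 * k * z)
    frame = background * (1.0 + fringes)
    nx, ny, _ = spec.shape
    spectra = np.broadcast_to(frame, (nx, ny, n)).copy()
    return RawSpectra(
        spectra=spectra,
        wavelengths_nm=lam,
        background=background,
        lateral_pitch_um=spec.lateral_pitch_um,
        refractive_index=spec.refractive_index,
    )


def sample_vessels(
    spec: PhantomSpec,
    n_lymphatic: int,
    n_vein: int,
    rng: np.random.Generator,
    depth_range_um: tuple[float, float] = (100.0, 400.0),
    radius_range_um: tuple[float, float] = (30.0, 70.0),
    deficit_db: float = 15.0,
) -> list[Vessel]:
    """Draw a plausible vessel population for an eye-like phantom.

    Vessels run roughly along ``y`` at physical depths within
    ``depth_range_um`` below the (flat part of the) surface, but lie at an
    angle to the scan direction — each drifts laterally across the volume
    — so successive B-scans see the cross-sections at shifting positions,
    as they do when real tissue is scanned at an arbitrary orientation.
    Lymphatic vessels additionally wander and vary in calibre along their
    length; veins are straight with a constant radius.
    """
    nx, ny, nz = spec.shape
    pz = spec.physical_pitch_um
    vessels: list[Vessel] = []
    kinds = ["lymphatic"] * n_lymphatic + ["vein"] * n_vein
    for kind in kinds:
        n_pts = 8
        ys = np.linspace(0, ny - 1, n_pts)
        x0 = rng.uniform(0.15 * nx, 0.85 * nx)
        drift = rng.uniform(-0.35, 0.35) * nx        # lateral run across the scan
        depth_um = rng.uniform(*depth_range_um)
        z0 = spec.surface_offset_px + depth_um / pz
        r_mean = rng.uniform(*radius_range_um)
        x_line = x0 + drift * np.linspace(-0.5, 0.5, n_pts)
        if kind == "lymphatic":
            xs = x_line + np.cumsum(rng.normal(0, 0.04 * nx, n_pts))
            zs = z0 + np.cumsum(rng.normal(0, 2.0, n_pts))
            radii = np.clip(r_mean * rng.uniform(0.5, 1.5, n_pts),
                            radius_range_um[0] * 0.5, radius_range_um[1] * 1.5)
        else:
            xs = x_line
            zs = np.full(n_pts, z0)
            radii = np.full(n_pts, r_mean)
        xs = np.clip(xs, 1, nx - 2)
        zs = np.clip(zs, spec.surface_offset_px + radii / pz + 2, nz - 2)
        centerline = np.stack([xs, ys, zs], axis=1)
        vessels.append(Vessel(centerline, radii, kind=kind, deficit_db=deficit_db))
    return vessels
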