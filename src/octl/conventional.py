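"""Threshold-based OCT lymphangiography with attenuation compensation.

Transparent (lymph- or aqueous-humor-filled) vessels appear as low-signal
tubes in an OCT scan, but the raw signal also decays with depth through
tissue attenuation and the axial system response, so a single global
threshold cannot separate vessels from deep tissue.  This module removes
both confounds before thresholding:

1. ``estimate_system_response`` recovers the combined confocal x roll-off
   response ``H(z)`` from a scan of a homogeneous low-scattering phantom
   of known attenuation ``mu_cal``.
2. ``correct_system`` subtracts ``H(z)`` from every A-scan.
3. ``fit_attenuation`` fits the corrected log signal of each A-scan to the
   single-scattering model ``I(z) = I0 * exp(-2*mu*z)`` — a straight line
   in dB vs physical depth — by ordinary least squares; the attenuation
   coefficient is ``mu = -slope * ln(10) / 20`` per A-scan.
4. ``compensate`` adds the fitted decay back, yielding tissue of nearly
   constant brightness in which vessels keep their signal deficit.
5. ``threshold_vessels`` applies a constant dB threshold below the tissue
   surface, which ``detect_surface`` finds with a per-B-scan Canny edge
   detector.
6. ``flatten_and_crop`` aligns every A-scan to the detected surface and
   keeps the superficial ~500 um where vessels are reliably visible.

``run_conventional`` composes the full flow and returns the flattened,
cropped binary vessel labels together with the aligned intensity volume
used to train the learned segmenter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage.feature import canny

from .preprocess import DB_PER_NEPER, normalize_noise
from .volume import OCTVolume, VesselMask

__all__ = [
    "CalibrationProfile",
    "AttenuationMap",
    "SurfaceMap",
    "FitPolicy",
    "ConventionalConfig",
    "ConventionalResult",
    "estimate_system_response",
    "correct_system",
    "fit_attenuation",
    "compensate",
    "threshold_vessels",
    "detect_surface",
    "flatten_and_crop",
    "run_conventional",
]


@dataclass
class CalibrationProfile:
    """Depth profile of the combined system response, 0 dB at its peak."""

    h_db: np.ndarray
    mu_cal: float
    axial_pitch_um: float
    valid_depth_px: int            # profile measured up to this depth, flat beyond

    def __post_init__(self) -> None:
        self.h_db = np.asarray(self.h_db, dtype=np.float64)
        if not np.all(np.isfinite(self.h_db)):
            raise ValueError("system response profile contains non-finite values")


@dataclass
class AttenuationMap:
    """Per-A-scan attenuation fit: coefficient, window, goodness, validity."""

    mu: np.ndarray                 # (nx, ny) mm^-1
    window_start: np.ndarray       # (nx, ny) int, inclusive
    window_end: np.ndarray         # (nx, ny) int, inclusive
    r_squared: np.ndarray          # (nx, ny)
    valid: np.ndarray              # (nx, ny) bool


@dataclass
class SurfaceMap:
    """Integer surface depth index per A-scan."""

    data: np.ndarray
    reliable: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=int)


@dataclass
class FitPolicy:
    """Window rule for the per-A-scan attenuation fit.

    The fit runs from ``surface + guard_px`` down to the last sample whose
    *axially smoothed* signal (moving average of ``smooth_px`` samples)
    still sits ``noise_margin_db`` above the (normalized, 0 dB) noise
    floor; smoothing keeps isolated speckle spikes in the noise tail from
    dragging the window into pure noise.  A-scans whose window is shorter
    than ``min_window_px`` are flagged invalid.
    """

    guard_px: int = 5
    noise_margin_db: float = 3.0
    min_window_px: int = 20
    smooth_px: int = 15


@dataclass
class ConventionalConfig:
    """Tunable parameters of the conventional pipeline."""

    theta_db: Optional[float] = None   # absolute threshold; None = relative mode
    theta_rel_db: float = 10.0         # threshold = tissue mode - theta_rel_db
    crop_um: float = 500.0
    mu_cal: float = 0.0
    speckle_smooth_px: int = 3         # lateral mean filter before thresholding
    canny_sigma: float = 2.0
    canny_low: float = 0.1             # fractions of the gradient dynamic range
    canny_high: float = 0.3
    median_width: int = 15
    fit: FitPolicy = field(default_factory=FitPolicy)


def estimate_system_response(
    cal: OCTVolume,
    mu_cal: float = 0.0,
    homogeneity_bound_db: float = 8.0,
    noise_margin_db: float = 3.0,
) -> CalibrationProfile:
    """Estimate H(z) from a homogeneous calibration phantom scan.

    The laterally averaged dB profile of the phantom is the system response
    minus the known attenuation slope; adding ``2*mu_cal*z`` (in dB, over
    physical depth) back and re-zeroing at the peak isolates ``H(z)``.  The
    profile is only trusted where the mean signal sits at least
    ``noise_margin_db`` above the noise floor and is held flat beyond.
    """
    if not cal.noise_normalized:
        raise ValueError("calibration volume must be noise-normalized first")
    profile = cal.data.mean(axis=(0, 1)).astype(np.float64)
    lateral_sd = cal.data.std(axis=(0, 1))
    above = profile >= noise_margin_db
    if not np.any(above):
        raise ValueError("calibration scan has no signal above the noise floor")
    if float(np.median(lateral_sd[above])) > homogeneity_bound_db:
        raise ValueError("calibration not homogeneous")
    # longest prefix of usable depths
    first_bad = int(np.argmin(above)) if not np.all(above) else cal.nz
    valid = max(first_bad, 1)

    z_mm = cal.depth_axis_mm(physical=True)
    h = profile + 2.0 * mu_cal * z_mm * DB_PER_NEPER
    h[valid:] = h[valid - 1]
    h -= h[:valid].max()
    return CalibrationProfile(
        h_db=h,
        mu_cal=mu_cal,
        axial_pitch_um=cal.axial_pitch_um,
        valid_depth_px=valid,
    )


def correct_system(vol: OCTVolume, prof: CalibrationProfile) -> OCTVolume:
    """Subtract the system response from every A-scan."""
    if prof.h_db.size != vol.nz:
        raise ValueError(
            f"depth mismatch: profile {prof.h_db.size} vs volume {vol.nz}"
        )
    out = vol.with_data(vol.data - prof.h_db.astype(np.float32)[None, None, :])
    out.meta = dict(vol.meta, system_corrected=True)
    return out


def fit_attenuation(
    vol: OCTVolume,
    surface: SurfaceMap,
    policy: FitPolicy | None = None,
    noise_floor_db: float | np.ndarray = 0.0,
) -> AttenuationMap:
    """Per-A-scan least-squares fit of the single-scattering decay.

    The corrected log signal is linear in depth, ``dB(z) = a - 20*mu*z/ln10``
    with ``z`` in physical mm, so an ordinary least-squares line fit over
    the usable window yields ``mu = -slope * ln(10)/20``.  All sums are
    evaluated with per-A-scan window masks so the whole volume is fitted
    vectorized.

    ``noise_floor_db`` is the noise level against which the window margin
    is tested; system correction subtracts ``H(z)`` from the whole A-scan,
    lifting the floor from 0 dB to ``-H(z)``, so the corrected-volume
    caller passes that depth profile here.
    """
    policy = policy or FitPolicy()
    nx, ny, nz = vol.shape
    db = vol.data.astype(np.float64)
    z_mm = vol.depth_axis_mm(physical=True)[None, None, :]

    start = surface.data + policy.guard_px
    if policy.smooth_px > 1:
        smoothed = ndimage.uniform_filter1d(db, policy.smooth_px, axis=2)
    else:
        smoothed = db
    floor = np.asarray(noise_floor_db, dtype=np.float64)
    if floor.ndim == 1:
        floor = floor[None, None, :]
    above_margin = smoothed >= floor + policy.noise_margin_db
    any_sig = above_margin.any(axis=2)
    last = nz - 1 - np.argmax(above_margin[:, :, ::-1], axis=2)
    last = np.where(any_sig, last, -1)

    z_idx = np.arange(nz)[None, None, :]
    w = (z_idx >= start[:, :, None]) & (z_idx <= last[:, :, None])
    n = w.sum(axis=2)
    valid = n >= policy.min_window_px

    wf = w.astype(np.float64)
    sx = (wf * z_mm).sum(axis=2)
    sy = (wf * db).sum(axis=2)
    sxx = (wf * z_mm**2).sum(axis=2)
    sxy = (wf * z_mm * db).sum(axis=2)
    syy = (wf * db**2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        nd = np.where(n > 0, n, 1).astype(np.float64)
        cov = sxy - sx * sy / nd
        varx = sxx - sx**2 / nd
        vary = syy - sy**2 / nd
        slope = np.where(varx > 0, cov / np.where(varx > 0, varx, 1.0), 0.0)
        r2 = np.where(
            (varx > 0) & (vary > 1e-12),
            cov**2 / np.where((varx > 0) & (vary > 1e-12), varx * vary, 1.0),
            1.0,
        )
    mu = -slope * np.log(10.0) / 20.0
    mu = np.where(valid, mu, np.nan)
    return AttenuationMap(
        mu=mu,
        window_start=start,
        window_end=last,
        r_squared=r2,
        valid=valid,
    )


def compensate(vol: OCTVolume, att: AttenuationMap, surface: SurfaceMap) -> OCTVolume:
    """Add the fitted round-trip decay back below the surface.

    Valid A-scans gain ``2*mu*(z - surface)`` (in dB over physical depth)
    for ``z`` at or below the surface and are untouched above it; invalid
    A-scans pass through unchanged.
    """
    if att.mu.shape != vol.shape[:2]:
        raise ValueError("attenuation map does not match volume grid")
    nz = vol.nz
    depth_px = np.arange(nz)[None, None, :] - surface.data[:, :, None]
    depth_mm = np.maximum(depth_px, 0) * vol.physical_pitch_um * 1e-3
    mu = np.where(att.valid, att.mu, 0.0)[:, :, None]
    gain = 2.0 * mu * depth_mm * DB_PER_NEPER
    return vol.with_data(vol.data + gain.astype(np.float32))


def threshold_vessels(
    vol: OCTVolume, theta_db: float, surface: SurfaceMap
) -> VesselMask:
    """Constant-threshold segmentation of the compensated scan.

    A voxel is vessel iff its compensated signal is below ``theta_db`` and
    it lies strictly below the detected surface.
    """
    below = np.arange(vol.nz)[None, None, :] > surface.data[:, :, None]
    mask = (vol.data < theta_db) & below
    return VesselMask(
        data=mask,
        frame="native",
        provenance="conventional",
        physical_pitch_um=vol.physical_pitch_um,
    )


def detect_surface(
    vol: OCTVolume,
    sigma: float = 2.0,
    hysteresis: tuple[float, float] = (0.1, 0.3),
    median_width: int = 15,
    floor_clip_db: float = 3.0,
) -> SurfaceMap:
    """Detect the tissue surface with a per-B-scan Canny edge detector.

    Each B-scan is clipped from below at ``floor_clip_db`` (values within a
    few dB of the normalized 0 dB noise floor carry no structure, only
    speckle, and would otherwise seed spurious edges above the surface),
    then normalized to its dynamic range; the Canny hysteresis thresholds
    are the given fractions of the scan's gradient-magnitude range.  Per
    A-scan the shallowest edge pixel is taken as the surface, gaps are
    filled by lateral linear interpolation, and the resulting map is
    median-filtered.  A scan with no edges anywhere yields a zero map
    flagged unreliable.
    """
    nx, ny, nz = vol.shape
    low_f, high_f = hysteresis
    surf = np.full((nx, ny), -1, dtype=float)
    for y in range(ny):
        img = np.clip(vol.data[:, y, :].astype(np.float64), floor_clip_db, None)
        # a scan with essentially nothing above the clipped floor has no
        # tissue; occasional speckle spikes would otherwise masquerade as
        # edges because the hysteresis thresholds are gradient-relative
        if np.mean(img > floor_clip_db + 5.0) < 0.01:
            continue
        rng_db = img.max() - img.min()
        if rng_db <= 0:
            continue
        norm = (img - img.min()) / rng_db
        gmax = float(ndimage.gaussian_gradient_magnitude(norm, sigma=sigma).max())
        if gmax <= 0:
            continue
        edges = canny(
            norm,
            sigma=sigma,
            low_threshold=low_f * gmax,
            high_threshold=high_f * gmax,
        )
        has_edge = edges.any(axis=1)
        first = np.argmax(edges, axis=1)
        surf[has_edge, y] = first[has_edge]
        # fill gaps along x within the B-scan
        if has_edge.any() and not has_edge.all():
            xi = np.arange(nx)
            surf[~has_edge, y] = np.interp(xi[~has_edge], xi[has_edge], first[has_edge])

    missing = surf < 0
    reliable = True
    if missing.all():
        warnings.warn("no surface edges detected; surface map is unreliable")
        surf[:] = 0
        reliable = False
    elif missing.any():
        warnings.warn("some B-scans had no edges; surface interpolated laterally")
        # fill whole-B-scan gaps from neighbouring B-scans
        for x in range(nx):
            row = surf[x]
            bad = row < 0
            if bad.any():
                yi = np.arange(ny)
                row[bad] = np.interp(yi[bad], yi[~bad], row[~bad])
    w = max(1, min(median_width, nx, ny))
    filtered = ndimage.median_filter(surf, size=(w, w), mode="nearest")
    return SurfaceMap(
        data=np.clip(np.rint(filtered), 0, nz - 1).astype(int),
        reliable=reliable,
    )


def flatten_and_crop(
    data: Union[OCTVolume, VesselMask],
    surface: SurfaceMap,
    crop_um: float = 500.0,
    physical_pitch_um: float | None = None,
) -> Union[OCTVolume, VesselMask]:
    """Shift every A-scan so the surface sits at depth 0, then crop.

    Shifts are integer pixel counts (masks stay binary); samples vacated at
    the bottom are zero/False padded.  The crop depth is ``crop_um`` of
    *tissue* (physical) length.
    """
    is_vol = isinstance(data, OCTVolume)
    if is_vol:
        pitch = data.physical_pitch_um
        arr = data.data
        fill = np.float32(0.0)
    else:
        pitch = physical_pitch_um or data.physical_pitch_um
        if pitch is None:
            raise ValueError("mask carries no axial pitch; pass physical_pitch_um")
        arr = data.data
        fill = False
    nx, ny, nz = arr.shape
    crop_px = int(round(crop_um / pitch))
    if crop_px < 1 or crop_px > nz:
        raise ValueError(
            f"crop of {crop_um} um = {crop_px} px exceeds volume depth {nz}"
        )
    z_idx = surface.data[:, :, None] + np.arange(crop_px)[None, None, :]
    in_range = z_idx < nz
    flat = np.take_along_axis(
        arr, np.minimum(z_idx, nz - 1), axis=2
    )
    flat = np.where(in_range, flat, fill)
    if is_vol:
        out = data.with_data(flat)
        out.meta = dict(data.meta, frame="flattened", crop_um=crop_um)
        return out
    return VesselMask(
        data=flat,
        frame="flattened",
        provenance=data.provenance,
        crop_um=crop_um,
        physical_pitch_um=pitch,
    )


@dataclass
class ConventionalResult:
    """Everything the conventional pipeline produces."""

    mask: VesselMask               # flattened, cropped labels
    volume: OCTVolume              # flattened, cropped aligned intensity
    attenuation: AttenuationMap
    surface: SurfaceMap
    theta_db: float
    profile: CalibrationProfile
    native_mask: VesselMask        # pre-flattening mask, native frame


def tissue_mode_db(
    vol: OCTVolume, surface: SurfaceMap, crop_px: int, bin_db: float = 0.5
) -> float:
    """Histogram mode of below-surface voxels within the crop depth."""
    nz = vol.nz
    depth = np.arange(nz)[None, None, :] - surface.data[:, :, None]
    sel = (depth > 0) & (depth <= crop_px)
    vals = vol.data[sel]
    if vals.size == 0:
        raise ValueError("no below-surface voxels to estimate the tissue mode")
    edges = np.arange(vals.min(), vals.max() + bin_db, bin_db)
    if edges.size < 2:
        return float(vals.mean())
    hist, edges = np.histogram(vals, bins=edges)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def run_conventional(
    vol: OCTVolume,
    cal: OCTVolume,
    config: ConventionalConfig | None = None,
) -> ConventionalResult:
    """The full conventional OCTL flow.

    correct -> fit -> compensate -> threshold, with the surface detected on
    the original (uncorrected) volume, then flattening and cropping of both
    the binary labels and the intensity volume.  When no absolute threshold
    is configured, it is placed ``theta_rel_db`` below the post-compensation
    tissue mode.
    """
    config = config or ConventionalConfig()
    if not vol.noise_normalized:
        vol = normalize_noise(vol)
    if not cal.noise_normalized:
        cal = normalize_noise(cal)

    profile = estimate_system_response(cal, mu_cal=config.mu_cal)
    surface = detect_surface(
        vol,
        sigma=config.canny_sigma,
        hysteresis=(config.canny_low, config.canny_high),
        median_width=config.median_width,
    )
    corrected = correct_system(vol, profile)
    att = fit_attenuation(
        corrected, surface, config.fit, noise_floor_db=-profile.h_db
    )
    comp = compensate(corrected, att, surface)
    if config.speckle_smooth_px > 1:
        # fully developed speckle dominates the voxelwise dB variance; a
        # small lateral mean reduces it ~sqrt(k) so a constant threshold
        # separates the vessel deficit from speckle fluctuation; the filter
        # stays within each depth plane to avoid smearing the surface
        k = config.speckle_smooth_px
        comp = comp.with_data(ndimage.uniform_filter(comp.data, size=(k, k, 1)))

    crop_px = int(round(config.crop_um / vol.physical_pitch_um))
    if config.theta_db is not None:
        theta = config.theta_db
    else:
        theta = tissue_mode_db(comp, surface, crop_px) - config.theta_rel_db
    native_mask = threshold_vessels(comp, theta, surface)
    flat_mask = flatten_and_crop(native_mask, surface, config.crop_um)
    flat_vol = flatten_and_crop(vol, surface, config.crop_um)
    return ConventionalResult(
        mask=flat_mask,
        volume=flat_vol,
        attenuation=att,
        surface=surface,
        theta_db=float(theta),
        profile=profile,
        native_mask=native_mask,
    )
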