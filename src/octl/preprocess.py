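"""Spectral-domain OCT reconstruction and noise-floor normalization.

A spectral-domain system records one interferogram per A-scan, sampled on a
wavelength grid that is *non-uniform in wavenumber* ``k = 2*pi/lambda``.
Reconstruction subtracts the background (source) spectrum, linearly resamples
onto a uniform wavenumber grid, applies an apodization window, and
inverse-Fourier-transforms each spectrum; the squared magnitude of the
positive-depth half, in dB, is the depth-resolved backscatter profile.

The axial pitch of the reconstruction follows from the spectral span: with
``N`` uniform wavenumber samples covering a span ``Dk`` (rad/um), the depth
pixel spacing is ``pi / (N * dk)`` micrometres of optical path, where ``dk``
is the sample spacing.

After reconstruction the noise floor is estimated in a deep region where the
signal is fully attenuated and subtracted, so the noise level sits at 0 dB
and thresholds/deficits can be quoted on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import OCTVolume

__all__ = [
    "RawSpectra",
    "reconstruct",
    "normalize_noise",
    "optical_to_physical",
    "DB_PER_NEPER",
]

# 10/ln(10): converts a (natural-log) intensity decay rate into dB.
DB_PER_NEPER = 10.0 / np.log(10.0)

_WINDOWS = ("hann", "hamming", "rect")


@dataclass
class RawSpectra:
    """Raw interferogram frames from a spectral-domain OCT scan.

    ``spectra`` is shaped ``(nx, ny, n_spectral)`` in detector counts,
    ``wavelengths_nm`` is the strictly monotonic wavelength grid of the
    spectrometer, and ``background`` the source spectrum recorded without a
    sample (subtracted before resampling).
    """

    spectra: np.ndarray
    wavelengths_nm: np.ndarray
    background: np.ndarray
    lateral_pitch_um: tuple[float, float] = (13.0, 13.0)
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.spectra.ndim != 3:
            raise ValueError("spectra must be 3-D [x, y, spectral pixel]")
        d = np.diff(self.wavelengths_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength grid must be strictly monotonic")
        if self.wavelengths_nm.size != self.spectra.shape[2]:
            raise ValueError("wavelength grid length mismatch")
        if self.background.size != self.spectra.shape[2]:
            raise ValueError("background length must equal spectral dimension")

    @property
    def n_spectral(self) -> int:
        return self.spectra.shape[2]

    def wavenumbers(self) -> np.ndarray:
        """Wavenumber k = 2*pi/lambda (rad/um) for each spectral pixel."""
        return 2.0 * np.pi / (self.wavelengths_nm * 1e-3)

    def axial_pitch_um(self) -> float:
        """Depth pixel spacing (optical um) implied by the spectral span."""
        k = np.sort(self.wavenumbers())
        n = k.size
        dk = (k[-1] - k[0]) / (n - 1)
        return float(np.pi / (n * dk))

    def unambiguous_depth_um(self) -> float:
        """Maximum depth (optical um) representable without aliasing."""
        return self.axial_pitch_um() * (self.n_spectral // 2)


def _window(name: str, n: int) -> np.ndarray:
    if name == "hann":
        return np.hanning(n)
    if name == "hamming":
        return np.hamming(n)
    if name == "rect":
        return np.ones(n)
    raise ValueError(f"unknown apodization window {name!r}; choose from {_WINDOWS}")


def reconstruct(raw: RawSpectra, window: str = "hann") -> OCTVolume:
    """Reconstruct a log-intensity volume from raw spectra.

    Per A-scan: background subtraction, linear resampling onto a uniform
    wavenumber grid, apodization, inverse FFT; the output voxel value is
    ``10*log10(|A|^2)`` of the positive-depth half.  The result is *not*
    yet noise-normalized.

    All-zero spectra are tolerated (a warning is emitted and the A-scan
    reconstructs to the numerical floor).
    """
    if raw.n_spectral < 8:
        raise ValueError("need at least 8 spectral pixels to reconstruct")
    k = raw.wavenumbers()
    order = np.argsort(k)
    k_sorted = k[order]
    n = raw.n_spectral
    k_uniform = np.linspace(k_sorted[0], k_sorted[-1], n)

    nx, ny, _ = raw.spectra.shape
    if np.all(raw.spectra == 0):
        warnings.warn("all-zero spectra; reconstruction is noise-only")

    frames = raw.spectra - raw.background[None, None, :]
    frames = frames[:, :, order]
    # linear resampling in k, endpoints clamped by np.interp semantics
    resampled = np.empty_like(frames)
    flat = frames.reshape(-1, n)
    out = resampled.reshape(-1, n)
    for i in range(flat.shape[0]):
        out[i] = np.interp(k_uniform, k_sorted, flat[i])
    resampled *= _window(window, n)[None, None, :]

    ascans = np.fft.ifft(resampled, axis=2)[:, :, : n // 2]
    intensity = np.abs(ascans) ** 2
    floor = np.finfo(np.float64).tiny
    db = 10.0 * np.log10(np.maximum(intensity, floor))

    return OCTVolume(
        data=db.astype(np.float32),
        axial_pitch_um=raw.axial_pitch_um(),
        lateral_pitch_um=raw.lateral_pitch_um,
        refractive_index=raw.refractive_index,
        noise_normalized=False,
    )


def normalize_noise(
    vol: OCTVolume,
    noise_region: tuple[int, int] | None = None,
    surface: np.ndarray | None = None,
) -> OCTVolume:
    """Subtract the mean dB level of a fully attenuated deep region.

    ``noise_region`` is a half-open depth index range ``(start, stop)``;
    by default the deepest 10 % of samples.  The output's mean over the
    region is exactly 0 dB and the ``noise_normalized`` flag is set.  If a
    surface map is supplied and overlaps the region, a warning is issued
    (the region should contain only noise).
    """
    nz = vol.nz
    if noise_region is None:
        noise_region = (nz - max(1, nz // 10), nz)
    z0, z1 = noise_region
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"empty or out-of-range noise region {noise_region}")
    if surface is not None and np.any(np.asarray(surface) >= z0):
        # tissue signal reaching into the window biases the floor estimate
        warnings.warn("noise region overlaps detected tissue")
    level = float(vol.data[:, :, z0:z1].mean())
    out = vol.with_data(vol.data - level, noise_normalized=True)
    out.meta = dict(vol.meta, noise_level_db=level, noise_region=(int(z0), int(z1)))
    return out


def optical_to_physical(length: float, n: float = 1.4) -> float:
    """Convert optical path length to physical (tissue) length.

    OCT measures optical path; inside tissue of refractive index ``n`` a
    physical distance ``d`` appears as ``n*d``, so the physical length is
    the optical length divided by ``n``.  Units are preserved.
    """
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    return length / n
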