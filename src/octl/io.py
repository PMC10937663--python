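"""Readers and writers for volumes, masks, and raw spectra.

Volumes travel as multi-page TIFF (one page per B-scan, 32-bit float dB)
with a JSON sidecar (same path + ``.json``) holding pitches, flags and
provenance; masks as 8-bit 0/1 TIFF stacks with the same sidecar scheme.
Raw spectra use a single HDF5 container with datasets ``spectra``,
``wavelengths`` and ``background``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .preprocess import RawSpectra
from .volume import OCTVolume, VesselMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_raw_spectra",
    "write_raw_spectra",
]


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_volume(vol: OCTVolume, path) -> None:
    """Write a volume as a B-scan page stack plus JSON sidecar."""
    pages = np.transpose(vol.data, (1, 2, 0)).astype(np.float32)  # (ny, nz, nx)
    tifffile.imwrite(path, pages)
    meta = {
        "axial_pitch_um": vol.axial_pitch_um,
        "lateral_pitch_um": list(vol.lateral_pitch_um),
        "refractive_index": vol.refractive_index,
        "noise_normalized": vol.noise_normalized,
        "meta": _jsonable(vol.meta),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_volume(path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`.

    A missing sidecar falls back to defaults with a warning.
    """
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.transpose(pages, (2, 0, 1))                         # (nx, ny, nz)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    else:
        warnings.warn(f"no sidecar for {path}; assuming default metadata")
        meta = {}
    return OCTVolume(
        data=data,
        axial_pitch_um=meta.get("axial_pitch_um", 3.52),
        lateral_pitch_um=tuple(meta.get("lateral_pitch_um", (2.93, 2.93))),
        refractive_index=meta.get("refractive_index", 1.4),
        noise_normalized=meta.get("noise_normalized", False),
        meta=meta.get("meta", {}),
    )


def write_mask(mask: VesselMask, path) -> None:
    """Write a binary mask as an 8-bit 0/1 page stack plus sidecar."""
    pages = np.transpose(mask.data.astype(np.uint8), (1, 2, 0))
    tifffile.imwrite(path, pages)
    meta = {
        "frame": mask.frame,
        "provenance": mask.provenance,
        "crop_um": mask.crop_um,
        "physical_pitch_um": mask.physical_pitch_um,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_mask(path) -> VesselMask:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.transpose(pages, (2, 0, 1)) != 0
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    else:
        warnings.warn(f"no sidecar for {path}; assuming default metadata")
        meta = {}
    return VesselMask(
        data=data,
        frame=meta.get("frame", "native"),
        provenance=meta.get("provenance", "conventional"),
        crop_um=meta.get("crop_um"),
        physical_pitch_um=meta.get("physical_pitch_um"),
    )


def write_raw_spectra(raw: RawSpectra, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=raw.spectra)
        f.create_dataset("wavelengths", data=raw.wavelengths_nm)
        f.create_dataset("background", data=raw.background)
        f.attrs["lateral_pitch_um"] = raw.lateral_pitch_um
        f.attrs["refractive_index"] = raw.refractive_index


def read_raw_spectra(path) -> RawSpectra:
    with h5py.File(path, "r") as f:
        return RawSpectra(
            spectra=f["spectra"][...],
            wavelengths_nm=f["wavelengths"][...],
            background=f["background"][...],
            lateral_pitch_um=tuple(f.attrs.get("lateral_pitch_um", (2.93, 2.93))),
            refractive_index=float(f.attrs.get("refractive_index", 1.4)),
        )


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out
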