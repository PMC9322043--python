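"""Hypercube containers, ENVI-dialect I/O, calibration and ROI extraction.

A :class:`HyperCube` is a (lines, samples, bands) array with an ascending
wavelength axis.  Raw cubes hold camera counts; after white/dark calibration
they hold dimensionless transmittance.  The ENVI format here is the plain
raw-binary-plus-ASCII-header dialect: ``bil``/``bsq``/``bip`` interleaves are
accepted on read, ``bil`` little-endian float32 is written.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HyperCube",
    "SpectraTable",
    "RoiNotFoundError",
    "read_envi",
    "write_envi",
    "calibrate_cube",
    "segment_roi",
    "apply_mask_mean_spectrum",
    "crop_spectral_range",
]

# numpy dtypes for the ENVI "data type" header codes
_ENVI_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4"}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class RoiNotFoundError(ValueError):
    """Thresholding found no egg pixels."""


@dataclass
class HyperCube:
    """3-D spectral image: data[line, sample, band] with wavelengths in nm."""

    data: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise ValueError("bands dimension must match wavelength vector length")
        if self.wavelengths_nm.size > 1 and np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly ascending")

    @property
    def shape(self):
        return self.data.shape

    def band_index(self, nm: float) -> int:
        """Index of the band nearest a target wavelength (no interpolation)."""
        return int(np.argmin(np.abs(self.wavelengths_nm - nm)))


@dataclass
class SpectraTable:
    """n_samples x n_bands matrix of (mean ROI) spectra."""

    spectra: np.ndarray
    wavelengths_nm: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.spectra.shape[1] != self.wavelengths_nm.size:
            raise ValueError("spectra columns must match wavelength vector length")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:03d}" for i in range(self.spectra.shape[0])]
        if len(self.sample_ids) != self.spectra.shape[0]:
            raise ValueError("one sample id per spectrum required")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    def to_csv(self, path) -> None:
        """CSV with a wavelength header row; rows indexed by sample id."""
        df = pd.DataFrame(
            self.spectra,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{w:.2f}" for w in self.wavelengths_nm],
        )
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            spectra=df.to_numpy(dtype=float),
            wavelengths_nm=np.array([float(c) for c in df.columns]),
            sample_ids=[str(i) for i in df.index],
        )


# ---------------------------------------------------------------------------
# ENVI raw + header I/O


def write_envi(cube: HyperCube, path) -> None:
    """Write a cube as ENVI raw (bil, little-endian float32) plus ``.hdr``."""
    path = Path(path)
    lines, samples, bands = cube.shape
    data = np.ascontiguousarray(
        cube.data.astype("<f4").transpose(0, 2, 1)  # bil: line, band, sample
    )
    data.tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths_nm)
    hdr = (
        "ENVI\n"
        "description = {ovaspec synthetic transmittance cube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bil\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {" + wl + "}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)


def _parse_envi_header(text: str) -> dict:
    # join brace-delimited multi-line values before splitting into fields
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path) -> HyperCube:
    """Read an ENVI raw cube; header found at ``<path>.hdr`` or ``<stem>.hdr``."""
    path = Path(path)
    for cand in (path.with_suffix(path.suffix + ".hdr"), path.with_suffix(".hdr")):
        if cand.exists():
            hdr = _parse_envi_header(cand.read_text())
            break
    else:
        raise FileNotFoundError(f"no ENVI header found for {path}")

    lines = int(hdr["lines"])
    samples = int(hdr["samples"])
    bands = int(hdr["bands"])
    dtype = np.dtype(_ENVI_DTYPES[int(hdr["data type"])])
    if int(hdr.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    else:
        dtype = dtype.newbyteorder("<")
    offset = int(hdr.get("header offset", 0))
    interleave = hdr.get("interleave", "bil").lower()

    raw = np.fromfile(path, dtype=dtype, offset=offset, count=lines * samples * bands)
    if interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")

    wl_field = hdr.get("wavelength", "")
    wl = np.array(
        [float(v) for v in wl_field.strip("{} ").split(",") if v.strip()], dtype=float
    )
    if wl.size != bands:
        raise ValueError("header wavelength block does not match band count")
    return HyperCube(data, wl)


# ---------------------------------------------------------------------------
# Calibration, segmentation, spectra


def calibrate_cube(
    raw: HyperCube, white: HyperCube, dark: HyperCube, eps: float = 1e-6
) -> HyperCube:
    """White/dark calibration to transmittance: (I_o - I_d) / (I_w - I_d).

    Voxels where the white and dark references coincide (|I_w - I_d| < eps)
    carry no radiometric information; they are set to 0 and counted in the
    log so the output stays finite.
    """
    for other in (white, dark):
        if other.shape != raw.shape:
            raise ValueError("raw/white/dark cubes must share the same shape")
        if not np.array_equal(other.wavelengths_nm, raw.wavelengths_nm):
            raise ValueError("raw/white/dark cubes must share the wavelength grid")
    num = raw.data.astype(np.float64) - dark.data
    den = white.data.astype(np.float64) - dark.data
    bad = np.abs(den) < eps
    if bad.any():
        logger.warning("calibrate_cube: %d voxels with degenerate denominator set to 0",
                       int(bad.sum()))
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~bad)
    return HyperCube(out, raw.wavelengths_nm.copy())


def segment_roi(
    cube: HyperCube,
    band_nm: float = 700.4,
    threshold: float = 0.1,
    fill_holes: bool = False,
) -> np.ndarray:
    """Egg mask by thresholding the single high-transmission band image.

    Pixels strictly above ``threshold`` at the band nearest ``band_nm`` are
    ROI.  Optional hole-filling is off by default (plain thresholding).
    """
    band = cube.data[:, :, cube.band_index(band_nm)]
    mask = band > threshold
    if fill_holes:
        from scipy.ndimage import binary_fill_holes

        mask = binary_fill_holes(mask)
    if not mask.any():
        raise RoiNotFoundError(
            f"no pixel exceeds transmittance {threshold} at {band_nm} nm"
        )
    return mask


def apply_mask_mean_spectrum(cube: HyperCube, mask: np.ndarray) -> np.ndarray:
    """Per-band mean over ROI pixels; background contributes nothing."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask spatial shape must match cube")
    if not mask.any():
        raise RoiNotFoundError("empty mask: no ROI pixels to average")
    return cube.data[mask].mean(axis=0)


def crop_spectral_range(table: SpectraTable, min_nm: float = 435.0) -> SpectraTable:
    """Drop the low-SNR short-wavelength bands below ``min_nm``."""
    keep = table.wavelengths_nm >= min_nm
    if not keep.any():
        raise ValueError(f"no bands at or above {min_nm} nm")
    return SpectraTable(
        spectra=table.spectra[:, keep],
        wavelengths_nm=table.wavelengths_nm[keep],
        sample_ids=list(table.sample_ids),
    )
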