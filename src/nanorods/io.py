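"""Micrograph I/O and physical calibration.

A micrograph is a single-frame 2D grayscale intensity field with a physical
pixel size. Supported on-disk formats are MRC2014 (the native format of most
TEM acquisition software) and single-page grayscale TIFF. Intensities are
carried in native detector units; nothing in the pipeline depends on their
absolute scale because segmentation is locally adaptive.

The default calibration, 0.3482 nm/px, corresponds to a Talos F200C at
x45,000 nominal magnification on a 4k CMOS detector and is applied only when
neither the file header nor the caller provides a pixel size.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Fallback physical pixel size (nm) when no calibration is available.
DEFAULT_PIXEL_SIZE_NM = 0.3482

#: Minimum micrograph edge length (px); smaller arrays are not meaningful
#: inputs for adaptive thresholding with realistic block sizes.
MIN_DIM = 64


class CalibrationWarning(UserWarning):
    """Raised as a warning when the default pixel size is assumed."""


@dataclass
class Micrograph:
    """A calibrated 2D grayscale image.

    Parameters
    ----------
    pixels : ndarray
        2D array of intensities in arbitrary detector units.
    pixel_size_nm : float
        Physical edge length of one pixel, in nanometres.
    source_id : str
        Free-text provenance (file path or synthetic scene id).
    """

    pixels: np.ndarray
    pixel_size_nm: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"micrograph must be 2D, got {self.pixels.ndim} dimensions"
            )
        if min(self.pixels.shape) < MIN_DIM:
            raise ValueError(
                f"micrograph dimensions {self.pixels.shape} below minimum {MIN_DIM}"
            )
        if not np.issubdtype(self.pixels.dtype, np.number):
            raise ValueError(f"non-numeric pixel dtype {self.pixels.dtype}")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise ValueError("micrograph contains non-finite intensities")
        if not (np.isfinite(self.pixel_size_nm) and self.pixel_size_nm > 0):
            raise ValueError(f"invalid pixel_size_nm {self.pixel_size_nm!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def px_to_nm(value, pixel_size_nm: float, kind: str = "length"):
    """Convert a pixel measure to physical units.

    ``kind='length'`` multiplies by the pixel size; ``kind='area'`` by its
    square. Accepts scalars or arrays; values must be non-negative.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("pixel measures must be non-negative")
    if kind == "length":
        out = arr * pixel_size_nm
    elif kind == "area":
        out = arr * pixel_size_nm**2
    else:
        raise ValueError(f"kind must be 'length' or 'area', got {kind!r}")
    return float(out) if np.isscalar(value) else out


# ---------------------------------------------------------------------------
# MRC2014: minimal single-section reader/writer.
# Header is 1024 bytes of little-endian words; voxel size = CELLA / M.
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def _read_mrc(path: Path) -> tuple[np.ndarray, float | None]:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise IOError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[0:16])
        mx = struct.unpack("<i", header[28:32])[0]
        xlen = struct.unpack("<f", header[40:44])[0]
        nsymbt = struct.unpack("<i", header[92:96])[0]
        if mode not in _MRC_MODES:
            raise IOError(f"{path}: unsupported MRC mode {mode}")
        if nz != 1:
            raise ValueError(f"{path}: MRC stack with nz={nz}; expected a single frame")
        fh.seek(1024 + nsymbt)
        data = np.fromfile(fh, dtype=np.dtype(_MRC_MODES[mode]).newbyteorder("<"),
                           count=nx * ny)
    if data.size != nx * ny:
        raise IOError(f"{path}: truncated MRC data block")
    pixel_size_nm = None
    if mx > 0 and xlen > 0:
        pixel_size_nm = (xlen / mx) / 10.0  # Angstrom -> nm
    return data.reshape(ny, nx), pixel_size_nm


def _write_mrc(path: Path, pixels: np.ndarray, pixel_size_nm: float) -> None:
    """Write a single-frame float32 MRC2014 file (mode 2)."""
    data = np.ascontiguousarray(pixels, dtype="<f4")
    ny, nx = data.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)           # NX NY NZ MODE
    struct.pack_into("<3i", header, 28, nx, ny, 1)             # MX MY MZ
    apix = pixel_size_nm * 10.0
    struct.pack_into("<3f", header, 40, nx * apix, ny * apix, apix)  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)      # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)               # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))          # little-endian
    with open(path, "wb") as fh:
        fh.write(header)
        data.tofile(fh)


# ---------------------------------------------------------------------------
# TIFF: written with the pixel size embedded as JSON in ImageDescription.
# ---------------------------------------------------------------------------

def _read_tiff(path: Path) -> tuple[np.ndarray, float | None]:
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) > 1:
            warnings.warn(
                f"{path}: multi-page TIFF; using page 0 only", UserWarning
            )
        page = tif.pages[0]
        data = page.asarray()
        pixel_size_nm = None
        desc = page.description
        if desc:
            try:
                meta = json.loads(desc)
                pixel_size_nm = float(meta["pixel_size_nm"])
            except (ValueError, KeyError, TypeError):
                pixel_size_nm = None
    return data, pixel_size_nm


def load_micrograph(path, pixel_size_override: float | None = None) -> Micrograph:
    """Read a micrograph from an MRC2014 or grayscale TIFF file.

    The pixel size is taken from the file header when present, else from
    ``pixel_size_override``, else the default 0.3482 nm (with a warning).
    Multi-channel (RGB) or >2D images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".map", ".rec"):
        data, meta_ps = _read_mrc(path)
    elif suffix in (".tif", ".tiff"):
        data, meta_ps = _read_tiff(path)
    else:
        raise IOError(f"{path}: unrecognized micrograph format {suffix!r}")
    if data.ndim != 2:
        raise ValueError(
            f"{path}: expected single-frame grayscale image, got shape {data.shape}"
        )
    if pixel_size_override is not None:
        if not (np.isfinite(pixel_size_override) and pixel_size_override > 0):
            raise ValueError(f"invalid pixel_size_override {pixel_size_override!r}")
    pixel_size = meta_ps if meta_ps else pixel_size_override
    if pixel_size is None:
        warnings.warn(
            f"{path}: no pixel size in metadata or override; "
            f"assuming {DEFAULT_PIXEL_SIZE_NM} nm/px",
            CalibrationWarning,
        )
        pixel_size = DEFAULT_PIXEL_SIZE_NM
    return Micrograph(pixels=data, pixel_size_nm=float(pixel_size),
                      source_id=str(path))


def save_micrograph(micrograph: Micrograph, path) -> None:
    """Write a micrograph to TIFF (pixel size in ImageDescription JSON) or MRC."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        desc = json.dumps({"pixel_size_nm": micrograph.pixel_size_nm})
        tifffile.imwrite(path, micrograph.pixels, description=desc)
    elif suffix in (".mrc", ".map", ".rec"):
        _write_mrc(path, micrograph.pixels, micrograph.pixel_size_nm)
    else:
        raise IOError(f"{path}: unrecognized output format {suffix!r}")
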