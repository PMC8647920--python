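"""Core image container, file I/O and intensity normalization.

Every stage of the restoration pipeline exchanges :class:`Image` objects:
2-D grayscale rasters with double-precision intensities. After
:func:`normalize_intensity` intensities live in [0, 1]; all stage parameters
(noise sigmas, regularization weights) are defined on that scale so defaults
are portable across cameras.

Coordinates are 0-based ``(row, col)`` with row 0 at the top.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "Image",
    "ImageIOError",
    "UnsupportedInputError",
    "ValidationError",
    "load_image",
    "save_image",
    "normalize_intensity",
]


class ImageIOError(IOError):
    """Raised when a file cannot be read or written."""


class UnsupportedInputError(ValueError):
    """Raised for inputs outside the supported single-frame grayscale model."""


class ValidationError(ValueError):
    """Raised when an argument violates a documented precondition."""


@dataclass(frozen=True)
class Image:
    """A single grayscale micrograph.

    Parameters
    ----------
    pixels
        2-D float array of intensities. Stored as float64.
    pixel_size_nm
        Optional physical pixel size; carried through the pipeline but never
        required by any algorithm.
    """

    pixels: np.ndarray
    pixel_size_nm: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError(f"Image requires a 2-D array, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError(f"Image requires positive dimensions, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("Image intensities must all be finite")
        if self.pixel_size_nm is not None and not self.pixel_size_nm > 0:
            raise ValidationError("pixel_size_nm must be positive when given")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Image":
        """New Image with replaced pixel data, keeping the pixel size."""
        return Image(pixels, pixel_size_nm=self.pixel_size_nm)


# ---------------------------------------------------------------------------
# minimal MRC mode-2 support (fixed 1024-byte header + raw float32 grid)

_MRC_HEADER_SIZE = 1024


def _read_mrc(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(_MRC_HEADER_SIZE)
        if len(header) < _MRC_HEADER_SIZE:
            raise ImageIOError(f"Truncated MRC header in {path}")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        if nz > 1:
            raise UnsupportedInputError(
                f"{path}: multi-frame MRC stacks (nz={nz}) are not supported"
            )
        if mode != 2:
            raise UnsupportedInputError(
                f"{path}: only MRC mode 2 (float32) is supported, got mode {mode}"
            )
        data = np.fromfile(fh, dtype="<f4", count=nx * ny)
    if data.size != nx * ny:
        raise ImageIOError(f"Truncated MRC data in {path}")
    # MRC stores x fastest: row-major (ny, nx)
    return data.reshape(ny, nx).astype(np.float64)


def _write_mrc(path: Path, arr: np.ndarray) -> None:
    ny, nx = arr.shape
    header = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx, my, mz
    struct.pack_into("<3f", header, 40, float(nx), float(ny), 1.0)  # cell
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into("<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(header)
        arr.astype("<f4").tofile(fh)


# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".png":
        return "png"
    if suffix == ".mrc":
        return "mrc"
    raise UnsupportedInputError(f"Cannot infer image format from suffix {suffix!r}")


def load_image(
    path: Union[str, Path],
    format: str = "auto",
    pixel_size_nm: Optional[float] = None,
) -> Image:
    """Load a single grayscale frame, discarding any embedded metadata.

    Multi-channel (RGB/RGBA) inputs are reduced by per-pixel channel
    averaging; multi-frame stacks are rejected. Intensities are returned as
    recorded — call :func:`normalize_intensity` before running the pipeline.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"No such image file: {path}")
    fmt = _infer_format(path) if format == "auto" else format
    try:
        if fmt == "tiff":
            arr = np.asarray(tifffile.imread(path))
        elif fmt == "png":
            arr = np.asarray(iio.imread(path))
        elif fmt == "mrc":
            arr = _read_mrc(path)
        else:
            raise UnsupportedInputError(f"Unknown format {fmt!r}")
    except (UnsupportedInputError, ImageIOError):
        raise
    except Exception as exc:  # decoding failure of whatever backend
        raise ImageIOError(f"Could not read {path}: {exc}") from exc

    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            arr = arr[:, :, :3].mean(axis=2)  # channel average; alpha dropped
        else:
            raise UnsupportedInputError(
                f"{path}: multi-frame stacks of shape {arr.shape} are not supported"
            )
    elif arr.ndim != 2:
        raise UnsupportedInputError(f"{path}: expected a 2-D frame, got shape {arr.shape}")
    return Image(arr.astype(np.float64), pixel_size_nm=pixel_size_nm)


def save_image(img: Image, path: Union[str, Path], bit_depth: str = "float") -> None:
    """Write an image as TIFF/PNG/MRC.

    ``bit_depth`` is one of ``{"8", "16", "float"}``. Integer depths rescale
    linearly from [min, max] to the full integer range (a constant image maps
    to 0). ``"float"`` is lossless for TIFF (float64) and stored as float32
    for MRC; PNG supports only the integer depths.
    """
    path = Path(path)
    if not path.parent.exists():
        raise ImageIOError(f"Parent directory does not exist: {path.parent}")
    fmt = _infer_format(path)
    bit_depth = str(bit_depth)
    arr = img.pixels

    if bit_depth in ("8", "16"):
        lo, hi = float(arr.min()), float(arr.max())
        scale = (255.0 if bit_depth == "8" else 65535.0)
        if hi > lo:
            quant = np.round((arr - lo) / (hi - lo) * scale)
        else:
            quant = np.zeros_like(arr)
        out = quant.astype(np.uint8 if bit_depth == "8" else np.uint16)
    elif bit_depth == "float":
        if fmt == "png":
            raise UnsupportedInputError("PNG does not support float output")
        out = arr  # kept float64 for TIFF; MRC writer narrows to float32
    else:
        raise ValidationError(f"bit_depth must be '8', '16' or 'float', got {bit_depth!r}")

    try:
        if fmt == "tiff":
            tifffile.imwrite(path, out)
        elif fmt == "png":
            iio.imwrite(path, out)
        elif fmt == "mrc":
            _write_mrc(path, np.asarray(out, dtype=np.float64))
    except Exception as exc:
        raise ImageIOError(f"Could not write {path}: {exc}") from exc


def normalize_intensity(img: Image) -> Image:
    """Affinely map intensities onto [0, 1].

    The map preserves intensity ordering. A constant image maps to all 0.5 by
    convention so degenerate inputs still flow through the pipeline.
    """
    arr = img.pixels
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        out = (arr - lo) / (hi - lo)
    else:
        out = np.full_like(arr, 0.5)
    return img.with_pixels(out)
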