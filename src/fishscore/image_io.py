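"""Reading RGB FISH images and splitting them into normalized channels.

Two-probe FISH slides are photographed as RGB images in which the blue
channel carries the DAPI nuclear counterstain, the red channel the HER2
probe signals and the green channel the CEP17 signals.  Everything
downstream of this module works on floating-point intensities in [0, 1],
so the bit depth of the camera (8 or 16 bit) is dealt with exactly once,
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "RgbImage",
    "ImageFormatError",
    "read_rgb",
    "split_channels",
    "normalize",
    "denormalize",
    "write_gray_tiff",
]


class ImageFormatError(ValueError):
    """Raised when a file decodes but is not a 3-channel RGB image."""


@dataclass(frozen=True)
class RgbImage:
    """Raw RGB image: integer channel matrices plus the declared bit depth.

    Channel matrices keep the raw integer intensities so that round trips
    to disk are lossless; ``split_channels`` produces the normalized
    floating-point views used by the analysis.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("channel matrices must share one shape")
        top = 2**self.bit_depth - 1
        for name, ch in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            if ch.ndim != 2:
                raise ValueError(f"{name} channel must be 2-D")
            if ch.size and (int(ch.min()) < 0 or int(ch.max()) > top):
                raise ValueError(
                    f"{name} channel exceeds the {self.bit_depth}-bit range [0, {top}]"
                )

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]


def _bit_depth_of(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ImageFormatError(f"unsupported sample dtype {dtype}; expected uint8 or uint16")


def read_rgb(path: str | Path) -> RgbImage:
    """Read a TIFF or PNG file as an :class:`RgbImage`.

    The channel order is fixed to (R, G, B) regardless of the file
    dialect.  RGBA input is accepted: the alpha channel is dropped with a
    logged warning, a common microscopy-export dialect.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ImageFormatError
        If the file is not a 3-channel (or RGBA) 8/16-bit image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise ImageFormatError(
            f"{path.name}: expected 3 channels, got a single-channel image"
        )
    if arr.ndim != 3:
        raise ImageFormatError(f"{path.name}: unsupported image layout {arr.shape}")
    if arr.shape[2] == 4:
        logger.warning("%s: RGBA input, dropping the alpha channel", path.name)
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ImageFormatError(
            f"{path.name}: expected 3 channels, got {arr.shape[2]}"
        )
    depth = _bit_depth_of(arr.dtype)
    return RgbImage(
        red=arr[:, :, 0].copy(),
        green=arr[:, :, 1].copy(),
        blue=arr[:, :, 2].copy(),
        bit_depth=depth,
    )


def normalize(raw: np.ndarray, bit_depth: int) -> np.ndarray:
    """Scale raw integer intensities to floats in [0, 1].

    Divides by ``2**bit_depth - 1`` so that the full-scale value maps to
    exactly 1.0.  Values outside the declared bit depth raise a
    ``ValueError`` rather than being clipped silently.
    """
    raw = np.asarray(raw)
    top = 2**bit_depth - 1
    if raw.size and (float(raw.min()) < 0 or float(raw.max()) > top):
        raise ValueError(f"intensities exceed the declared {bit_depth}-bit range")
    return raw.astype(np.float64) / top


def denormalize(values: np.ndarray, bit_depth: int) -> np.ndarray:
    """Inverse of :func:`normalize`: floats in [0,1] back to raw integers."""
    top = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.rint(np.asarray(values) * top).astype(dtype)


def split_channels(img: RgbImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the (red, green, blue) channels normalized to [0, 1]."""
    return (
        normalize(img.red, img.bit_depth),
        normalize(img.green, img.bit_depth),
        normalize(img.blue, img.bit_depth),
    )


def write_gray_tiff(path: str | Path, values: np.ndarray) -> None:
    """Write a real-valued matrix as a 32-bit float TIFF (debug output)."""
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))
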