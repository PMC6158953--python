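"""Grayscale image and binary mask types with PNG/TIFF readers and writers.

Coordinates are row-major, 0-based ``(row, col)`` with the origin at the
top-left pixel.  All in-memory intensities are 8-bit (0-255); 16-bit input
files are rescaled on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ContractError, FormatError

__all__ = [
    "GrayImage",
    "BinaryMask",
    "read_gray_image",
    "write_gray_image",
    "write_mask",
]

# ITU-R BT.601 luminance weights; any convex weighting maps grey to itself.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of 8-bit grey levels.

    Parameters
    ----------
    pixels
        2-D integer array; every value must lie in [0, 255].
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ContractError(f"pixels must be a non-empty 2-D grid, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.round(px)):
                raise ContractError("pixel intensities must be integers")
        if px.min() < 0 or px.max() > 255:
            raise ContractError("pixel intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", np.ascontiguousarray(px, dtype=np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.pixels.size

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D grid over {0, 1}; 1 marks foreground."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ContractError(f"labels must be a non-empty 2-D grid, got shape {lab.shape}")
        if not np.isin(lab, (0, 1)).all():
            raise ContractError("mask labels must be 0 or 1")
        object.__setattr__(self, "labels", np.ascontiguousarray(lab, dtype=np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a PNG or TIFF file as an 8-bit grayscale image.

    Multi-channel input is collapsed to luminance; 16-bit input is rescaled
    to [0, 255] by dividing by the image maximum (microscopy TIFFs rarely use
    the full 16-bit range) and rounding half-up.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"zero-size image: {path}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 2:  # gray + alpha
            arr = arr[:, :, 0]
        else:  # RGB(A)
            arr = _round_half_up(arr[:, :, :3].astype(np.float64) @ _LUMA)
    if arr.ndim != 2:
        raise FormatError(f"unsupported image layout with shape {arr.shape}: {path}")
    arr = arr.astype(np.float64)
    if arr.max() > 255:
        arr = _round_half_up(arr * (255.0 / arr.max()))
    return GrayImage(arr.astype(np.int64))


def write_gray_image(image: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF (format chosen by extension)."""
    iio.imwrite(Path(path), image.pixels)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG with foreground 255 and background 0."""
    iio.imwrite(Path(path), (mask.labels * np.uint8(255)))
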