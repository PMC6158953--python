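"""Boundary extraction and the per-pixel, per-terminal lambda multipliers.

At boundary pixels the object-terminal link is boosted by ``c_p`` and the
background-terminal link is zeroed; everywhere else both multipliers are 1,
so an empty boundary map reduces exactly to a single static lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, grey_dilation, grey_erosion

from .core_image import BinaryMask, GrayImage
from .errors import ContractError, DegenerateHistogramError
from .seeding import otsu_threshold

__all__ = [
    "BoundaryMap",
    "LambdaField",
    "extract_boundaries",
    "lambda_coefficient",
    "build_lambda_field",
]


@dataclass(frozen=True)
class BoundaryMap:
    """Boolean grid, true where a pixel belongs to the boundary set."""

    members: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.members)
        if m.ndim != 2:
            raise ContractError("boundary map must be 2-D")
        object.__setattr__(self, "members", m.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.members.shape

    @property
    def is_empty(self) -> bool:
        return not self.members.any()

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "BoundaryMap":
        return cls(np.zeros(shape, dtype=bool))

    def to_mask(self) -> BinaryMask:
        return BinaryMask(self.members.astype(np.uint8))


@dataclass(frozen=True)
class LambdaField:
    """Per-pixel multipliers applied to the base parameter ``lambda1``.

    ``o_mult`` scales object-terminal t-links, ``b_mult`` background-terminal
    ones; the effective lambda at a link is ``lambda1 * multiplier``.
    """

    lambda1: float
    c_p: float
    o_mult: np.ndarray
    b_mult: np.ndarray

    def __post_init__(self) -> None:
        if self.lambda1 <= 0:
            raise ContractError(f"lambda1 must be > 0, got {self.lambda1}")
        if self.c_p < 0:
            raise ContractError(f"c_p must be >= 0, got {self.c_p}")
        o = np.asarray(self.o_mult, dtype=np.float64)
        b = np.asarray(self.b_mult, dtype=np.float64)
        if o.shape != b.shape or o.ndim != 2:
            raise ContractError("multiplier grids must be 2-D and share a shape")
        object.__setattr__(self, "o_mult", o)
        object.__setattr__(self, "b_mult", b)

    @property
    def shape(self) -> tuple[int, int]:
        return self.o_mult.shape

    @classmethod
    def static(cls, shape: tuple[int, int], lambda1: float) -> "LambdaField":
        """A field equivalent to one global static lambda (no boundary set)."""
        return build_lambda_field(BoundaryMap.empty(shape), lambda1, c_p=1.0)


_SELEM = np.ones((3, 3), dtype=bool)


def _band(mask: np.ndarray, convention: str, radius: int) -> np.ndarray:
    selem = np.ones((2 * radius + 1,) * 2, dtype=bool) if radius != 1 else _SELEM
    if convention == "inner":
        return mask & ~binary_erosion(mask, structure=selem)
    if convention == "outer":
        return binary_dilation(mask, structure=selem) & ~mask
    if convention == "both":
        return binary_dilation(mask, structure=selem) & ~binary_erosion(mask, structure=selem)
    raise ContractError(f"unknown boundary convention {convention!r}")


def extract_boundaries(
    image: GrayImage,
    method: str = "otsu-gradient",
    convention: str = "inner",
    radius: int = 1,
    gradient_threshold: float | None = None,
) -> BoundaryMap:
    """Extract the boundary pixel set used to adapt lambda.

    ``otsu-gradient`` (default) takes the morphological gradient band of the
    binary Otsu mask; ``inner`` keeps the object-side rim of each component
    (a 10x10 filled square yields its 36 perimeter pixels), ``outer``/``both``
    widen the band outward.  ``gradient-threshold`` instead thresholds the
    grey-level morphological gradient of the image itself.

    A degenerate Otsu histogram produces an empty map (no adaptation) with a
    warning rather than an error, so adaptive pipelines can fall back to the
    static behaviour.
    """
    if method == "otsu-gradient":
        try:
            t = otsu_threshold(image)
        except DegenerateHistogramError:
            warnings.warn("degenerate Otsu histogram; boundary set is empty", stacklevel=2)
            return BoundaryMap.empty(image.shape)
        return BoundaryMap(_band(image.pixels > t, convention, radius))
    if method == "gradient-threshold":
        selem = np.ones((2 * radius + 1,) * 2)
        grad = grey_dilation(image.pixels, footprint=selem).astype(np.int16) - grey_erosion(
            image.pixels, footprint=selem
        ).astype(np.int16)
        if gradient_threshold is None:
            gradient_threshold = grad.max() / 2.0
        return BoundaryMap(grad > gradient_threshold)
    raise ContractError(f"unknown boundary method {method!r}")


def lambda_coefficient(is_boundary: bool, terminal: str, c_p: float) -> float:
    """Multiplier c: boundary pixels get c_p toward O and 0 toward B, others 1."""
    if terminal not in ("O", "B"):
        raise ContractError(f"terminal must be 'O' or 'B', got {terminal!r}")
    if not is_boundary:
        return 1.0
    return float(c_p) if terminal == "O" else 0.0


def build_lambda_field(boundaries: BoundaryMap, lambda1: float, c_p: float) -> LambdaField:
    """Populate the multiplier grids from a boundary map (effective lambda =
    ``lambda1 * multiplier``; boundary O-links get ``lambda1 * c_p``)."""
    if lambda1 <= 0:
        raise ContractError(f"lambda1 must be > 0, got {lambda1}")
    b = boundaries.members
    return LambdaField(
        lambda1=float(lambda1),
        c_p=float(c_p),
        o_mult=np.where(b, float(c_p), 1.0),
        b_mult=np.where(b, 0.0, 1.0),
    )
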