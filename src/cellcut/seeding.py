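"""Foreground/background seed selection.

Seeds come from user scribbles (interactive mode) or from an Otsu
pre-segmentation of the image itself (automatic mode).  Otsu ties are broken
toward the lowest optimal threshold so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_image import GrayImage
from .errors import ContractError, DegenerateHistogramError, EmptySeedError

__all__ = ["SeedSet", "otsu_threshold", "auto_seeds", "scribble_seeds"]


@dataclass(frozen=True)
class SeedSet:
    """Disjoint foreground and background sample-pixel coordinate sets."""

    foreground: frozenset[tuple[int, int]]
    background: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        fg = frozenset((int(r), int(c)) for r, c in self.foreground)
        bg = frozenset((int(r), int(c)) for r, c in self.background)
        if fg & bg:
            raise ContractError("foreground and background seeds must be disjoint")
        object.__setattr__(self, "foreground", fg)
        object.__setattr__(self, "background", bg)

    def validate_for(self, image: GrayImage) -> None:
        """Check bounds against *image* and that both classes are non-empty."""
        if not self.foreground or not self.background:
            raise EmptySeedError("both seed classes must be non-empty")
        h, w = image.shape
        for r, c in self.foreground | self.background:
            if not (0 <= r < h and 0 <= c < w):
                raise ContractError(f"seed ({r}, {c}) outside image bounds {image.shape}")

    def fg_intensities(self, image: GrayImage) -> np.ndarray:
        return _intensities(self.foreground, image)

    def bg_intensities(self, image: GrayImage) -> np.ndarray:
        return _intensities(self.background, image)


def _intensities(coords: frozenset[tuple[int, int]], image: GrayImage) -> np.ndarray:
    if not coords:
        return np.empty(0, dtype=np.uint8)
    idx = np.array(sorted(coords), dtype=np.intp)
    return image.pixels[idx[:, 0], idx[:, 1]]


def _between_class_variance(hist: np.ndarray) -> np.ndarray:
    """Between-class variance for every threshold t in 0..255.

    Class "black" is {intensity <= t}, class "white" is {intensity > t};
    thresholds leaving either class empty get variance -inf.
    """
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist).astype(np.float64)
    w1 = total - w0
    cum_mean = np.cumsum(levels * hist)
    grand = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand - cum_mean) / w1
        var_b = w0 * w1 * (mu0 - mu1) ** 2
    var_b[(w0 == 0) | (w1 == 0)] = -np.inf
    return var_b


def otsu_threshold(image: GrayImage) -> int:
    """Threshold t maximizing between-class variance of the 256-bin histogram.

    Pixels > t are "white" (foreground candidates), pixels <= t are "black".
    Ties are broken by the lowest optimal threshold.

    Raises
    ------
    DegenerateHistogramError
        If the image has fewer than two distinct intensity values.
    """
    hist = np.bincount(image.pixels.ravel(), minlength=256)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("image has a single intensity value; no Otsu split")
    var_b = _between_class_variance(hist)
    return int(np.argmax(var_b))  # argmax returns the first (lowest) maximizer


def auto_seeds(image: GrayImage, erosion_radius: int = 0) -> SeedSet:
    """Seeds from the Otsu segmentation: white pixels -> foreground samples,
    black pixels -> background samples.

    With the default ``erosion_radius=0`` every pixel is used, so the two
    seed sets partition the image.  A positive radius erodes each class away
    from the Otsu boundary for robustness experiments.
    """
    t = otsu_threshold(image)
    white = image.pixels > t
    black = ~white
    if erosion_radius > 0:
        from scipy.ndimage import binary_erosion

        selem = np.ones((2 * erosion_radius + 1,) * 2, dtype=bool)
        white_e = binary_erosion(white, structure=selem)
        black_e = binary_erosion(black, structure=selem)
        if white_e.any() and black_e.any():
            white, black = white_e, black_e
    return SeedSet(
        foreground=frozenset(zip(*np.nonzero(white))),
        background=frozenset(zip(*np.nonzero(black))),
    )


def scribble_seeds(scribble: np.ndarray, image: GrayImage) -> SeedSet:
    """Seeds from a scribble label mask: 0 unlabeled, 1 foreground, 2 background."""
    scribble = np.asarray(scribble)
    if scribble.shape != image.shape:
        raise ContractError(
            f"scribble shape {scribble.shape} does not match image shape {image.shape}"
        )
    if not np.isin(scribble, (0, 1, 2)).all():
        bad = sorted(set(np.unique(scribble)) - {0, 1, 2})
        raise ContractError(f"illegal scribble labels {bad}; allowed values are 0, 1, 2")
    fg = frozenset(zip(*np.nonzero(scribble == 1)))
    bg = frozenset(zip(*np.nonzero(scribble == 2)))
    if not fg or not bg:
        raise EmptySeedError("scribble must label at least one pixel of each class")
    return SeedSet(foreground=fg, background=bg)


def scribble_from_csv(path, image: GrayImage) -> SeedSet:
    """Seeds from a CSV of ``row,col,label`` records (label 1=fg, 2=bg)."""
    records = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    scribble = np.zeros(image.shape, dtype=np.uint8)
    for r, c, lab in records:
        scribble[r, c] = lab
    return scribble_seeds(scribble, image)
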