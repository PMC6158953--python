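"""Seed-driven intensity appearance model and its negative-log data costs."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_image import GrayImage
from .errors import ContractError, EmptySeedError
from .seeding import SeedSet

__all__ = ["AppearanceModel", "build_model", "data_cost", "DEFAULT_SMOOTHING"]

#: Pseudo-count added to every histogram bin so unseen intensities get a
#: large but finite cost instead of an infinite (hard-constraint) one.
DEFAULT_SMOOTHING = 1e-6


@dataclass(frozen=True)
class AppearanceModel:
    """Normalized 256-bin foreground/background intensity histograms."""

    fg_hist: np.ndarray
    bg_hist: np.ndarray
    smoothing: float

    def __post_init__(self) -> None:
        for name in ("fg_hist", "bg_hist"):
            h = np.asarray(getattr(self, name), dtype=np.float64)
            if h.shape != (256,):
                raise ContractError(f"{name} must have 256 bins, got shape {h.shape}")
            if abs(h.sum() - 1.0) > 1e-9:
                raise ContractError(f"{name} must sum to 1 (got {h.sum():.12f})")
            if self.smoothing > 0 and not (h > 0).all():
                raise ContractError(f"{name} has empty bins despite smoothing > 0")
            object.__setattr__(self, name, h)

    def cost_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-intensity (cost_fg, cost_bg) lookup tables, -log of each histogram."""
        with np.errstate(divide="ignore"):
            return -np.log(self.fg_hist), -np.log(self.bg_hist)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fg_hist": self.fg_hist.tolist(),
            "bg_hist": self.bg_hist.tolist(),
            "smoothing": self.smoothing,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "AppearanceModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            fg_hist=np.array(payload["fg_hist"]),
            bg_hist=np.array(payload["bg_hist"]),
            smoothing=float(payload["smoothing"]),
        )


def _histogram(intensities: np.ndarray, smoothing: float) -> np.ndarray:
    counts = np.bincount(intensities, minlength=256).astype(np.float64) + smoothing
    return counts / counts.sum()


def build_model(
    image: GrayImage, seeds: SeedSet, smoothing: float = DEFAULT_SMOOTHING
) -> AppearanceModel:
    """Build normalized fg/bg intensity histograms from the seed pixels."""
    if smoothing < 0:
        raise ContractError("smoothing pseudo-count must be >= 0")
    if not seeds.foreground or not seeds.background:
        raise EmptySeedError("cannot build an appearance model from an empty seed class")
    seeds.validate_for(image)
    return AppearanceModel(
        fg_hist=_histogram(seeds.fg_intensities(image), smoothing),
        bg_hist=_histogram(seeds.bg_intensities(image), smoothing),
        smoothing=smoothing,
    )


def data_cost(model: AppearanceModel, intensity: int) -> tuple[float, float]:
    """(cost_fg, cost_bg) = (-log P(I|fg), -log P(I|bg)), natural log."""
    if not 0 <= intensity <= 255 or intensity != int(intensity):
        raise ContractError(f"intensity must be an integer grey level in [0, 255], got {intensity}")
    cost_fg, cost_bg = model.cost_tables()
    return float(cost_fg[int(intensity)]), float(cost_bg[int(intensity)])
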