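"""Pipeline orchestration: interactive/automatic seeding crossed with a
static or boundary-adaptive lambda, plus the lambda-sweep and noise
experiment harnesses."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .adaptivity import LambdaField, build_lambda_field, extract_boundaries
from .appearance import DEFAULT_SMOOTHING, build_model
from .core_image import BinaryMask, GrayImage
from .errors import ContractError
from .graphcut import build_graph, energy, estimate_sigma, labeling_from_cut, max_flow
from .metrics import confusion, report
from .seeding import SeedSet, auto_seeds
from .synth import add_salt_pepper

__all__ = ["SegmentationResult", "segment", "segment_auto", "lambda_sweep", "noise_experiment"]

MODES = ("static", "adaptive")


@dataclass(frozen=True)
class SegmentationResult:
    mask: BinaryMask
    energy: float
    flow: float
    config_echo: dict


def _lambda_field(image: GrayImage, mode: str, lambda1: float, c_p: float,
                  boundary_kwargs: dict | None) -> LambdaField:
    if mode == "static":
        return LambdaField.static(image.shape, lambda1)
    boundaries = extract_boundaries(image, **(boundary_kwargs or {}))
    if boundaries.is_empty:
        warnings.warn("empty boundary set; adaptive mode degenerates to static", stacklevel=3)
    return build_lambda_field(boundaries, lambda1, c_p)


def segment(
    image: GrayImage,
    seeds: SeedSet,
    mode: str = "static",
    lambda1: float = 20.0,
    c_p: float = 20.0,
    sigma: float | None = None,
    smoothing: float = DEFAULT_SMOOTHING,
    hard_seeds: bool = False,
    boundary_kwargs: dict | None = None,
) -> SegmentationResult:
    """Segment with seed-derived histograms and a min-cut.

    ``static`` uses one global lambda; ``adaptive`` extracts cell boundaries
    and boosts/zeroes their terminal links.  Seeds are soft (they only shape
    the histograms) unless ``hard_seeds`` adds large-capacity t-links.
    """
    if mode not in MODES:
        raise ContractError(f"mode must be one of {MODES}, got {mode!r}")
    if lambda1 <= 0:
        raise ContractError(f"lambda1 must be > 0, got {lambda1}")
    seeds.validate_for(image)
    model = build_model(image, seeds, smoothing)
    if sigma is None:
        sigma = estimate_sigma(image)
    field = _lambda_field(image, mode, lambda1, c_p, boundary_kwargs)
    graph = build_graph(image, model, field, sigma, hard_seeds=seeds if hard_seeds else None)
    flow, cut_side = max_flow(graph)
    mask = labeling_from_cut(cut_side, graph)
    return SegmentationResult(
        mask=mask,
        energy=energy(mask, image, model, field, sigma),
        flow=flow,
        config_echo={
            "mode": mode,
            "lambda1": lambda1,
            "c_p": c_p,
            "sigma": float(sigma),
            "smoothing": smoothing,
            "hard_seeds": hard_seeds,
            "seed_provenance": "caller",
            "n_fg_seeds": len(seeds.foreground),
            "n_bg_seeds": len(seeds.background),
        },
    )


def segment_auto(image: GrayImage, mode: str = "static", **params) -> SegmentationResult:
    """Fully automatic pipeline: Otsu-derived seeds, then `segment`."""
    result = segment(image, auto_seeds(image), mode=mode, **params)
    result.config_echo["seed_provenance"] = "otsu-auto"
    return result


def lambda_sweep(
    image: GrayImage,
    seeds: SeedSet,
    mode: str,
    grid,
    ground_truth: BinaryMask,
    **params,
) -> pd.DataFrame:
    """One segmentation per lambda; returns a (lambda, AI, F1) table."""
    grid = list(grid)
    if not grid:
        raise ContractError("lambda grid must be non-empty")
    if any(lam <= 0 for lam in grid):
        raise ContractError("all lambda values must be > 0")
    rows = []
    for lam in grid:
        res = segment(image, seeds, mode=mode, lambda1=float(lam), **params)
        m = report(confusion(res.mask, ground_truth))
        rows.append({"lambda": float(lam), "ai": m.ai, "f1": m.f1})
    return pd.DataFrame(rows)


def noise_experiment(
    image: GrayImage,
    seeds: SeedSet,
    mode: str,
    densities,
    ground_truth: BinaryMask,
    lambda1: float = 20.0,
    rng_seed: int = 0,
    **params,
) -> pd.DataFrame:
    """Salt-and-pepper robustness at a constant lambda.

    Each density corrupts the image independently (one RNG substream per
    density), the corrupted image is segmented with the given seeds, and F1
    against the clean ground truth is tabulated.
    """
    densities = list(densities)
    if any(not 0 <= d <= 0.5 for d in densities):
        raise ContractError("noise densities must lie in [0, 0.5]")
    rows = []
    for i, density in enumerate(densities):
        noisy = add_salt_pepper(image, density, seed=rng_seed * 100003 + i)
        res = segment(noisy, seeds, mode=mode, lambda1=lambda1, **params)
        m = report(confusion(res.mask, ground_truth))
        rows.append({"density": float(density), "f1": m.f1})
    return pd.DataFrame(rows)
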