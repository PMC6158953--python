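"""s/t segmentation graph construction, max-flow/min-cut, and labeling energy.

T-link convention: the object-terminal (source) link of pixel ``a`` carries
the *background* data cost and the background-terminal (sink) link carries
the *foreground* data cost.  A pixel kept on the source (foreground) side of
the cut severs its sink link and therefore pays the foreground cost — the
energy-consistent reading.  Boosting the source link and zeroing the sink
link of a boundary pixel biases it toward foreground under this convention.

n-link weights are NOT scaled by lambda: lambda weighs only the data term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _maxflow
from .adaptivity import LambdaField
from .appearance import AppearanceModel
from .core_image import BinaryMask, GrayImage
from .errors import ContractError
from .seeding import SeedSet

__all__ = [
    "SegGraph",
    "smoothness_weight",
    "estimate_sigma",
    "build_graph",
    "max_flow",
    "labeling_from_cut",
    "energy",
]

#: Capacity used for hard seed constraints (--hard-seeds).
HARD_SEED_CAPACITY = 1e6


@dataclass(frozen=True)
class SegGraph:
    """An s/t graph over pixel nodes with 4-connected n-links.

    Pixel nodes are numbered row-major ``0 .. n_pixels-1``; the object
    terminal O (source) and background terminal B (sink) come last.  Every
    undirected edge is stored as a pair of residual arcs with equal capacity
    (arc ``i ^ 1`` is the partner of arc ``i``).
    """

    shape: tuple[int, int]
    sigma: float
    arc_tail: np.ndarray
    arc_head: np.ndarray
    arc_cap: np.ndarray

    def __post_init__(self) -> None:
        cap = np.asarray(self.arc_cap, dtype=np.float64)
        if (cap < 0).any() or not np.isfinite(cap).all():
            raise ContractError("all capacities must be finite and >= 0")
        object.__setattr__(self, "arc_cap", cap)

    @property
    def n_pixels(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def source(self) -> int:
        return self.n_pixels

    @property
    def sink(self) -> int:
        return self.n_pixels + 1

    @property
    def n_nodes(self) -> int:
        return self.n_pixels + 2

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        """Undirected edge list (u, v, capacity), one entry per arc pair."""
        return [
            (int(self.arc_tail[i]), int(self.arc_head[i]), float(self.arc_cap[i]))
            for i in range(0, len(self.arc_cap), 2)
        ]

    def to_dimacs(self, path: str | Path) -> None:
        """Dump in DIMACS max-flow format (1-based node ids) for cross-checks."""
        lines = [f"p max {self.n_nodes} {len(self.arc_cap)}"]
        lines.append(f"n {self.source + 1} s")
        lines.append(f"n {self.sink + 1} t")
        for t, h, c in zip(self.arc_tail, self.arc_head, self.arc_cap):
            lines.append(f"a {t + 1} {h + 1} {c!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def smoothness_weight(ia: float, ib: float, sigma: float) -> float:
    """Gaussian similarity exp(-(ia-ib)^2 / (2 sigma^2)), in (0, 1]."""
    if sigma <= 0:
        raise ContractError(f"sigma must be > 0, got {sigma}")
    d = float(ia) - float(ib)
    return math.exp(-(d * d) / (2.0 * sigma * sigma))


def estimate_sigma(image: GrayImage) -> float:
    """Similarity scale: standard deviation of 4-neighbor intensity differences.

    Falls back to 1.0 for images whose neighbor differences are all zero.
    """
    px = image.pixels.astype(np.float64)
    diffs = np.concatenate(
        [(px[:, 1:] - px[:, :-1]).ravel(), (px[1:, :] - px[:-1, :]).ravel()]
    )
    if diffs.size == 0:
        return 1.0
    sd = float(diffs.std())
    return sd if sd > 0 else 1.0


def _neighbor_pairs(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row-major pixel index pairs for the 4-neighborhood: all rightward
    pairs first, then all downward pairs."""
    h, w = shape
    idx = np.arange(h * w, dtype=np.int64).reshape(h, w)
    u = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    v = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    return u, v


def build_graph(
    image: GrayImage,
    model: AppearanceModel,
    field: LambdaField,
    sigma: float,
    hard_seeds: SeedSet | None = None,
) -> SegGraph:
    """Assemble the s/t graph realizing the lambda-weighted energy.

    T-link capacities: ``a-O = lambda1 * o_mult[a] * cost_bg(I_a)`` and
    ``a-B = lambda1 * b_mult[a] * cost_fg(I_a)``; n-links carry the Gaussian
    smoothness weight of the two intensities.  ``hard_seeds`` adds a large
    constant to the O-link of foreground seeds and the B-link of background
    seeds (Boykov-Jolly style hard constraints, off by default).
    """
    if sigma <= 0:
        raise ContractError(f"sigma must be > 0, got {sigma}")
    if field.shape != image.shape:
        raise ContractError(f"lambda field shape {field.shape} != image shape {image.shape}")
    h, w = image.shape
    n = h * w
    intens = image.pixels.ravel().astype(np.intp)
    cost_fg_tab, cost_bg_tab = model.cost_tables()

    o_cap = field.lambda1 * field.o_mult.ravel() * cost_bg_tab[intens]
    b_cap = field.lambda1 * field.b_mult.ravel() * cost_fg_tab[intens]
    if hard_seeds is not None:
        o_cap = o_cap.copy()
        b_cap = b_cap.copy()
        for r, c in hard_seeds.foreground:
            o_cap[r * w + c] += HARD_SEED_CAPACITY
        for r, c in hard_seeds.background:
            b_cap[r * w + c] += HARD_SEED_CAPACITY

    ui, vi = _neighbor_pairs(image.shape)
    px = image.pixels.ravel().astype(np.float64)
    n_cap = np.exp(-((px[ui] - px[vi]) ** 2) / (2.0 * sigma * sigma))

    pixels = np.arange(n, dtype=np.int64)
    source = np.full(n, n, dtype=np.int64)
    sink = np.full(n, n + 1, dtype=np.int64)
    # undirected edges in deterministic order: per-pixel O-link then B-link,
    # then n-links; each expands to a forward/backward arc pair
    tails = np.empty(2 * n + len(ui), dtype=np.int64)
    heads = np.empty_like(tails)
    caps = np.empty(tails.shape, dtype=np.float64)
    tails[0:2 * n:2], heads[0:2 * n:2], caps[0:2 * n:2] = source, pixels, o_cap
    tails[1:2 * n:2], heads[1:2 * n:2], caps[1:2 * n:2] = pixels, sink, b_cap
    tails[2 * n:], heads[2 * n:], caps[2 * n:] = ui, vi, n_cap

    arc_tail = np.repeat(tails, 2)
    arc_head = np.repeat(heads, 2)
    arc_tail[1::2], arc_head[1::2] = heads, tails
    arc_cap = np.repeat(caps, 2)
    return SegGraph(
        shape=image.shape, sigma=float(sigma),
        arc_tail=arc_tail, arc_head=arc_head, arc_cap=arc_cap,
    )


def max_flow(graph: SegGraph) -> tuple[float, np.ndarray]:
    """Solve max-flow/min-cut by BFS augmenting paths (Edmonds-Karp).

    Returns the flow value (= minimum cut capacity) and a boolean array over
    all nodes, true for nodes on the source (object) side of the cut.
    Deterministic for a fixed graph.
    """
    flow, reach = _maxflow.solve(
        graph.n_nodes, graph.source, graph.sink,
        graph.arc_tail, graph.arc_head, graph.arc_cap,
    )
    return flow, reach


def labeling_from_cut(cut_side: np.ndarray, graph: SegGraph) -> BinaryMask:
    """Foreground = pixels on the object-terminal side of the cut."""
    return BinaryMask(cut_side[: graph.n_pixels].reshape(graph.shape).astype(np.uint8))


def energy(
    labeling: BinaryMask,
    image: GrayImage,
    model: AppearanceModel,
    field: LambdaField,
    sigma: float,
) -> float:
    """Lambda-weighted data cost of the labels plus smoothness penalties for
    every 4-neighbor pair with unequal labels; equals the capacity of the cut
    induced by the labeling."""
    if labeling.shape != image.shape or field.shape != image.shape:
        raise ContractError("labeling, image and lambda field shapes must agree")
    if sigma <= 0:
        raise ContractError(f"sigma must be > 0, got {sigma}")
    lab = labeling.labels.astype(bool)
    intens = image.pixels.astype(np.intp)
    cost_fg_tab, cost_bg_tab = model.cost_tables()
    data = np.where(
        lab,
        field.lambda1 * field.b_mult * cost_fg_tab[intens],
        field.lambda1 * field.o_mult * cost_bg_tab[intens],
    ).sum()
    ui, vi = _neighbor_pairs(image.shape)
    flat_lab = lab.ravel()
    px = image.pixels.ravel().astype(np.float64)
    cut = flat_lab[ui] != flat_lab[vi]
    smooth = np.exp(-((px[ui[cut]] - px[vi[cut]]) ** 2) / (2.0 * sigma * sigma)).sum()
    return float(data + smooth)
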