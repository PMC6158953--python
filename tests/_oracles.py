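"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths they check: min cuts are
found by enumerating partitions, energies by enumerating labelings, and the
Otsu threshold by a direct per-threshold scan.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def brute_force_min_cut(n_pixels, o_cap, b_cap, nlinks):
    """Minimum s/t cut by enumerating all 2^n pixel partitions.

    ``o_cap[i]``/``b_cap[i]`` are the terminal link capacities of pixel i and
    ``nlinks`` is a list of ``(i, j, cap)``.  Returns ``(value, best_set)``
    where ``best_set`` is the lexicographically first optimal source side.
    """
    best_val = np.inf
    best_set = None
    for bits in product((0, 1), repeat=n_pixels):
        val = 0.0
        for i in range(n_pixels):
            val += b_cap[i] if bits[i] else o_cap[i]
        for i, j, cap in nlinks:
            if bits[i] != bits[j]:
                val += cap
        if val < best_val - 1e-12:
            best_val = val
            best_set = bits
    return best_val, best_set


def exhaustive_min_energy(image, model, field, sigma, energy_fn, mask_cls):
    """Minimum energy over every binary labeling of a tiny image."""
    h, w = image.shape
    best = np.inf
    for bits in product((0, 1), repeat=h * w):
        labeling = mask_cls(np.array(bits, dtype=np.uint8).reshape(h, w))
        e = energy_fn(labeling, image, model, field, sigma)
        if e < best:
            best = e
    return best


def otsu_scan(pixels):
    """Lowest threshold maximizing between-class variance, by direct scan."""
    flat = np.asarray(pixels).ravel().astype(np.float64)
    best_t, best_var = None, -np.inf
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size
        w1 = hi.size
        var_b = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if best_t is None or var_b > best_var + 1e-9 * max(1.0, abs(best_var)):
            best_var, best_t = var_b, t
    return best_t


def trapezoid_auc(points):
    """Independent trapezoid integration of sorted ROC points."""
    pts = sorted({(float(f), float(t)) for f, t in points} | {(0.0, 0.0), (1.0, 1.0)})
    area = 0.0
    for (f0, t0), (f1, t1) in zip(pts, pts[1:]):
        area += (f1 - f0) * (t0 + t1) / 2.0
    return area
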