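"""Independent brute-force oracles used by the test suite.

These are deliberately naive reimplementations (plain Python loops and
dictionaries) kept separate from the package so they cannot share code
paths with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_pair_entropy(
    x, y, theta_idx, polarity, intensity,
    n_d_bins: int = 500, n_alpha_bins: int = 48, n_sections: int = 24,
    d_max: float | None = None,
) -> float:
    """O(n^2) second-order edge-orientation entropy in bits.

    Ordered-pair enumeration: every (i, j), i != j, deposits the intensity
    product under (distance bin, signed orientation difference of j relative
    to i, orientation section of i); per-cell section histograms are
    normalised and their Shannon entropies averaged over occupied cells.
    """
    n = len(x)
    o360 = [int(theta_idx[i]) + n_sections * (polarity[i] < 0) for i in range(n)]
    if d_max is None:
        d_max = math.hypot(max(x) - min(x), max(y) - min(y))
    if d_max <= 0:
        d_max = 1.0
    weights: dict[tuple[int, int, int], float] = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.hypot(x[i] - x[j], y[i] - y[j])
            db = min(int(d / d_max * n_d_bins), n_d_bins - 1)
            diff = (o360[j] - o360[i]) % (2 * n_sections)
            ab = int(diff * n_alpha_bins / (2 * n_sections))
            key = (db, ab, int(theta_idx[i]))
            weights[key] = weights.get(key, 0.0) + float(intensity[i] * intensity[j])
    cells: dict[tuple[int, int], dict[int, float]] = {}
    for (db, ab, sec), w in weights.items():
        cells.setdefault((db, ab), {})[sec] = w
    entropies = []
    for hist in cells.values():
        total = sum(hist.values())
        entropies.append(
            -sum((v / total) * math.log2(v / total) for v in hist.values())
        )
    return float(np.mean(entropies))


def naive_box_count(mask: np.ndarray, box: int) -> int:
    """Count occupied box x box tiles by explicit iteration."""
    size = mask.shape[0]
    count = 0
    for r0 in range(0, size, box):
        for c0 in range(0, size, box):
            if mask[r0 : r0 + box, c0 : c0 + box].any():
                count += 1
    return count
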