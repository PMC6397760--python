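"""Independent brute-force oracles used to verify the pipeline algorithms.

Each oracle re-states its operation's contract with the simplest possible
machinery (full pairwise scans, linear search, exhaustive enumeration) and
shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_treetops(
    heights: np.ndarray,
    mask: np.ndarray,
    pixel_size: float,
    top_min_height: float,
    window_slope: float,
    window_intercept: float,
) -> list[tuple[int, int]]:
    """Exhaustive re-check of the variable-window local-maximum rule.

    For every masked candidate pixel the *entire* masked grid is scanned
    (no windowed slicing): the pixel is a top iff no strictly higher
    masked pixel, and no equal-height masked pixel earlier in row-major
    order, lies within the window radius of its centre.  Returns (row,
    col) pairs sorted by descending height then row-major order.
    """
    n_rows, n_cols = heights.shape
    masked = [
        (r, c)
        for r in range(n_rows)
        for c in range(n_cols)
        if mask[r, c] and math.isfinite(heights[r, c])
    ]
    tops = []
    for r, c in masked:
        h = heights[r, c]
        if h < top_min_height:
            continue
        radius = window_slope * h + window_intercept
        is_top = True
        for r2, c2 in masked:
            if (r2, c2) == (r, c):
                continue
            d = math.hypot((r2 - r) * pixel_size, (c2 - c) * pixel_size)
            if d > radius:
                continue
            h2 = heights[r2, c2]
            if h2 > h or (h2 == h and (r2 * n_cols + c2) < (r * n_cols + c)):
                is_top = False
                break
        if is_top:
            tops.append((r, c))
    tops.sort(key=lambda rc: (-heights[rc], rc[0], rc[1]))
    return tops


def priority_flood_oracle(
    heights: np.ndarray,
    retained: np.ndarray,
    markers: list[tuple[int, int]],
) -> np.ndarray:
    """Marker flood by linear scan over an explicit offer list.

    Markers are seeded with labels 1..K in the given order.  At each step
    the pending offer with the greatest height (then the earliest creation
    order) is selected by linear search and its pixel's 4-neighbours are
    claimed.  No priority queue is used.
    """
    labels = np.zeros(heights.shape, dtype=int)
    offers: list[tuple[float, int, int, int]] = []
    order = 0
    for k, (r, c) in enumerate(markers, start=1):
        labels[r, c] = k
        offers.append((float(heights[r, c]), order, r, c))
        order += 1
    n_rows, n_cols = heights.shape
    while offers:
        best_i = 0
        for i in range(1, len(offers)):
            hi, oi = offers[i][0], offers[i][1]
            hb, ob = offers[best_i][0], offers[best_i][1]
            if hi > hb or (hi == hb and oi < ob):
                best_i = i
        _, _, r, c = offers.pop(best_i)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols:
                if retained[nr, nc] and labels[nr, nc] == 0:
                    labels[nr, nc] = labels[r, c]
                    offers.append((float(heights[nr, nc]), order, nr, nc))
                    order += 1
    return labels


def min_cost_matching_by_enumeration(cost: np.ndarray) -> float:
    """Minimum total cost of a one-to-one matching, by exhausting all
    injections of the smaller side into the larger."""
    n, m = cost.shape
    if n > m:
        return min_cost_matching_by_enumeration(cost.T)
    best = math.inf
    for perm in itertools.permutations(range(m), n):
        total = sum(cost[i, j] for i, j in enumerate(perm))
        best = min(best, total)
    return best


def nearest_centroid_label(
    vector: np.ndarray, centroids: dict[str, np.ndarray]
) -> str:
    """Label of the Euclidean-nearest centroid; ties to the smaller name."""
    return min(
        sorted(centroids),
        key=lambda k: (float(np.linalg.norm(vector - centroids[k])), k),
    )
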