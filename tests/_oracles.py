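"""Independent brute-force oracles used by the tests.

These deliberately share no code path with the package: the Otsu oracle
minimizes the exact within-class variance by exhaustive search with integer
cross-multiplication, the enlargement oracle computes all-pairs distances,
and the region-stats oracle recomputes every field from the sorted value
list with plain Python loops.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np


def otsu_brute_force(pixels: np.ndarray, bit_depth: int) -> int:
    """Exhaustively minimize the within-class variance over all 256 candidate
    thresholds of a 256-bin histogram spanning the nominal range; ties break
    toward the smallest threshold. Comparison is exact (integer rationals):
    minimizing v0+v1 is equivalent to maximizing M0²/W0 + M1²/W1, compared by
    cross-multiplication."""
    bw = (1 << bit_depth) // 256
    hist = np.bincount((pixels // bw).ravel(), minlength=256)
    counts = [int(c) for c in hist]
    best_num, best_den, best_t = -1, 1, None
    for t in range(255):
        w0 = sum(counts[: t + 1])
        w1 = sum(counts[t + 1 :])
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum(b * c for b, c in enumerate(counts[: t + 1]))
        m1 = sum(b * c for b, c in enumerate(counts) if b > t)
        num = m0 * m0 * w1 + m1 * m1 * w0  # maximize num / (w0*w1)
        den = w0 * w1
        if best_t is None or num * best_den > best_num * den:
            best_num, best_den, best_t = num, den, t
    return (best_t + 1) * bw - 1


def enlarge_brute_force(mask: np.ndarray, distance_px: float) -> np.ndarray:
    """All-pairs Euclidean-distance region growth on a small grid."""
    pts = np.argwhere(mask)
    out = np.zeros_like(mask, dtype=bool)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            d2 = ((pts[:, 0] - i) ** 2 + (pts[:, 1] - j) ** 2).min()
            out[i, j] = math.sqrt(d2) <= distance_px + 1e-9
    return out


def region_stats_naive(values: Sequence[int]) -> Dict[str, float]:
    """Recompute every measurement field from the sorted value list."""
    vals = sorted(int(v) for v in values)
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    sd = math.sqrt(var)
    if sd > 0:
        skew = sum((v - mean) ** 3 for v in vals) / n / sd ** 3
        kurt = sum((v - mean) ** 4 for v in vals) / n / sd ** 4 - 3.0
    else:
        skew = kurt = 0.0
    freq: Dict[int, int] = {}
    for v in vals:
        freq[v] = freq.get(v, 0) + 1
    top = max(freq.values())
    mode = min(v for v, c in freq.items() if c == top)
    return {
        "n": n,
        "mean": mean,
        "std_dev": sd,
        "min": vals[0],
        "max": vals[-1],
        "raw_integrated_density": sum(vals),
        "median": vals[(n - 1) // 2],
        "mode": mode,
        "skewness": skew,
        "kurtosis": kurt,
    }


def nearest_outside_distance(
    centroid_rc: Tuple[float, float], roi: np.ndarray
) -> float:
    """Brute-force minimum distance (px) from a point to any pixel outside roi."""
    best = math.inf
    for r in range(roi.shape[0]):
        for c in range(roi.shape[1]):
            if not roi[r, c]:
                best = min(
                    best, math.hypot(centroid_rc[0] - r, centroid_rc[1] - c)
                )
    return best
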