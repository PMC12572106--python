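"""Independent oracles used by the test suite.

Each oracle recomputes an expected result by brute force or exact
arithmetic, on a code path deliberately disjoint from the implementation
it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def iou_1d(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / (max(a[1], b[1]) - min(a[0], b[0]))


def brute_force_match(
    annotations: list[tuple[float, float]],
    predictions: list[tuple[float, float]],
    threshold: float,
) -> tuple[int, float]:
    """(max pair count, max total IoU among max-count matchings), by
    exhaustive recursion over admissible edges."""
    edges = {}
    for i, a in enumerate(annotations):
        for j, p in enumerate(predictions):
            v = iou_1d(a, p)
            if v > threshold:
                edges[(i, j)] = v
    best = (0, 0.0)

    def recurse(j: int, used: frozenset, count: int, total: float) -> None:
        nonlocal best
        if j == len(predictions):
            if (count, total) > best:
                best = (count, round(total, 12))
            return
        recurse(j + 1, used, count, total)
        for i in range(len(annotations)):
            if i not in used and (i, j) in edges:
                recurse(j + 1, used | {i}, count + 1, total + edges[(i, j)])

    recurse(0, frozenset(), 0, 0.0)
    return best


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


def prune_peaks_brute_force(
    x: np.ndarray, height: float, distance: int
) -> list[int]:
    """Local maxima above ``height``, pruned so no two survive within
    ``distance`` samples: repeatedly keep the highest remaining maximum
    (ties: earliest) and drop its neighbours."""
    candidates = [
        i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]
        and x[i] >= height
    ]
    kept: list[int] = []
    remaining = sorted(candidates, key=lambda i: (-x[i], i))
    alive = set(candidates)
    for i in remaining:
        if i in alive:
            kept.append(i)
            alive -= {j for j in alive if j != i and abs(j - i) < distance}
    return sorted(kept)
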