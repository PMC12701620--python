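"""Independent brute-force oracles.

Deliberately naive implementations (explicit loops, BFS, exhaustive
enumeration) kept separate from the package code paths so they can serve as
ground truth in equivalence tests.
"""
from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_count(mask: np.ndarray, connectivity: int = 26) -> int:
    """Number of connected components by BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 26:
        offsets = [
            (di, dj, dk)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            for dk in (-1, 0, 1)
            if (di, dj, dk) != (0, 0, 0)
        ]
    elif connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        raise ValueError(connectivity)
    seen = np.zeros_like(mask)
    count = 0
    shape = mask.shape
    for start in zip(*np.nonzero(mask & ~seen)):
        if seen[start]:
            continue
        count += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            i, j, k = queue.popleft()
            for di, dj, dk in offsets:
                ni, nj, nk = i + di, j + dj, k + dk
                if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                    if mask[ni, nj, nk] and not seen[ni, nj, nk]:
                        seen[ni, nj, nk] = True
                        queue.append((ni, nj, nk))
    return count


def exposed_face_area(mask: np.ndarray, spacing) -> float:
    """Loop over every mask voxel and its 6 face neighbors."""
    mask = np.asarray(mask, dtype=bool)
    sx, sy, sz = spacing
    areas = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    total = 0.0
    shape = mask.shape
    for i, j, k in zip(*np.nonzero(mask)):
        for axis, (di, dj, dk) in enumerate(
            [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        ):
            for sign in (1, -1):
                ni, nj, nk = i + sign * di, j + sign * dj, k + sign * dk
                outside = not (
                    0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]
                ) or not mask[ni, nj, nk]
                if outside:
                    total += areas[axis]
    return total


def max_pairwise_distance(points: np.ndarray) -> float:
    """O(n^2) exhaustive maximum."""
    points = np.asarray(points, dtype=float)
    best = 0.0
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = float(np.linalg.norm(points[i] - points[j]))
            if d > best:
                best = d
    return best


def concordance_auc(pos, neg) -> float:
    """Pair-by-pair concordance count, ties worth 1/2."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_cutoff(pos, neg) -> tuple[float, float, float]:
    """Best (cutoff, sensitivity, specificity) over all adjacent-value
    midpoints, maximizing sens*spec; ties -> higher specificity, then lower
    cutoff.  Test-positive is value >= cutoff."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    values = np.unique(np.concatenate([pos, neg]))
    best = None
    for c in (values[:-1] + values[1:]) / 2.0:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        key = (-(sens * spec), -spec, c)
        if best is None or key < best[0]:
            best = (key, float(c), sens, spec)
    return best[1], best[2], best[3]


def sphere_voxel_count(center, radius, spacing, origin, shape) -> int:
    """Count voxel centers inside a sphere by direct iteration."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                p = np.asarray(origin) + np.asarray([i, j, k]) * np.asarray(spacing)
                if np.linalg.norm(p - np.asarray(center)) <= radius:
                    count += 1
    return count
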