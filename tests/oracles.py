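"""Independent reference implementations used as test oracles.

These deliberately use brute force / direct formula evaluation, not the
package's own code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def disk_pixel_count(center, radius, shape) -> int:
    """Exhaustive per-pixel Euclidean distance check."""
    n = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                n += 1
    return n


def plain_cross_entropy(probs: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Unweighted cross-entropy sum scaled by 1/K, evaluated naively."""
    total = 0.0
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            total -= np.log(max(probs[r, c, labels[r, c]], 1e-7))
    return total / k


def brute_force_match(detections, annotations, tolerance):
    """Enumerate all one-to-one assignments: maximize the number of pairs
    within tolerance, then minimize the total paired distance.

    Returns (n_matches, total_distance).  Exponential; use only for tiny
    point sets.
    """
    det = [tuple(p) for p in detections]
    ann = [tuple(p) for p in annotations]
    if len(det) > len(ann):
        det, ann = ann, det
    best = (0, 0.0)
    n = len(det)
    for subset in itertools.chain.from_iterable(
        itertools.combinations(range(n), size) for size in range(n + 1)
    ):
        for targets in itertools.permutations(range(len(ann)), len(subset)):
            dists = [
                np.hypot(det[i][0] - ann[j][0], det[i][1] - ann[j][1])
                for i, j in zip(subset, targets)
            ]
            if any(d > tolerance for d in dists):
                continue
            cand = (len(subset), sum(dists))
            if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
    return best


def greedy_match(detections, annotations, tolerance):
    """Greedy nearest-pair matching (cross-check lower bound on matches)."""
    det = [tuple(p) for p in detections]
    ann = [tuple(p) for p in annotations]
    pairs = sorted(
        (
            (np.hypot(d[0] - a[0], d[1] - a[1]), i, j)
            for i, d in enumerate(det)
            for j, a in enumerate(ann)
        ),
    )
    used_d, used_a = set(), set()
    n = 0
    for dist, i, j in pairs:
        if dist > tolerance or i in used_d or j in used_a:
            continue
        used_d.add(i)
        used_a.add(j)
        n += 1
    return n


def r_squared(pred, ann) -> float:
    """Closed-form 1 - SS_res / SS_tot."""
    pred = np.asarray(pred, float)
    ann = np.asarray(ann, float)
    ss_res = ((ann - pred) ** 2).sum()
    ss_tot = ((ann - ann.mean()) ** 2).sum()
    return 1 - ss_res / ss_tot
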