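"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: ray-triangle
intersection goes through an explicit plane intersection plus a
least-squares barycentric solve, and the histogram threshold oracle scans
every cut point recomputing both class variances from scratch.
"""

from __future__ import annotations

import numpy as np


def ray_triangle_oracle(origin, direction, tri):
    """Ray/triangle hit via plane intersection + barycentric containment.

    Returns the ray parameter t of the hit, or None for a miss.
    """
    v0, v1, v2 = (np.asarray(v, float) for v in tri)
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    n = np.cross(v1 - v0, v2 - v0)
    denom = n @ direction
    if abs(denom) < 1e-12:
        return None
    t = (n @ (v0 - origin)) / denom
    if t < 0:
        return None
    p = origin + t * direction
    A = np.column_stack([v1 - v0, v2 - v0])
    (u, v), *_ = np.linalg.lstsq(A, p - v0, rcond=None)
    if u >= 0 and v >= 0 and u + v <= 1:
        return float(t)
    return None


def otsu_intraclass(counts, centers, threshold):
    """Weighted intra-class variance of the split at ``threshold``."""
    counts = np.asarray(counts, float)
    centers = np.asarray(centers, float)
    lo = centers <= threshold
    w0, w1 = counts[lo].sum(), counts[~lo].sum()
    if w0 == 0 or w1 == 0:
        return np.inf
    m0 = (counts[lo] * centers[lo]).sum() / w0
    m1 = (counts[~lo] * centers[~lo]).sum() / w1
    v0 = (counts[lo] * (centers[lo] - m0) ** 2).sum() / w0
    v1 = (counts[~lo] * (centers[~lo] - m1) ** 2).sum() / w1
    return (w0 * v0 + w1 * v1) / counts.sum()


def otsu_bruteforce(counts, centers):
    """Exhaustive intra-class-variance minimization over all cut points."""
    counts = np.asarray(counts, float)
    centers = np.asarray(centers, float)
    best_thr, best_var = None, np.inf
    total = counts.sum()
    for k in range(len(counts) - 1):
        w0 = counts[: k + 1].sum()
        w1 = counts[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        m1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        v0 = (counts[: k + 1] * (centers[: k + 1] - m0) ** 2).sum() / w0
        v1 = (counts[k + 1 :] * (centers[k + 1 :] - m1) ** 2).sum() / w1
        intra = (w0 * v0 + w1 * v1) / total
        if intra < best_var:
            best_var, best_thr = intra, centers[k]
    return best_thr
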