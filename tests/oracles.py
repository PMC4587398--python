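"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: exhaustive
enumeration, direct textbook formulas and small-n recomputation only.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_integer_shift(reference: np.ndarray, moving: np.ndarray) -> tuple[int, int]:
    """Argmax of full circular cross-correlation over all integer shifts.

    Returns the shift (d_row, d_col) such that rolling ``reference`` by it
    best matches ``moving`` — i.e. the drift of the moving image.  Ties go
    to the smallest-magnitude shift.
    """
    h, w = reference.shape
    best = None
    for dr in range(h):
        for dc in range(w):
            score = float(np.sum(np.roll(reference, (dr, dc), axis=(0, 1)) * moving))
            sdr = dr - h if dr > h // 2 else dr
            sdc = dc - w if dc > w // 2 else dc
            key = (-score, sdr * sdr + sdc * sdc)
            if best is None or key < best[0]:
                best = (key, (sdr, sdc))
    return best[1]


def brute_force_upgma(points: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering by direct recomputation.

    Inter-cluster distance is recomputed at every step as the mean of all
    pairwise point distances between members.  Returns the sorted merge
    heights (n-1 of them).
    """
    points = np.asarray(points, float)
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            dist = float(np.mean([d[a, b] for a in clusters[i] for b in clusters[j]]))
            if best is None or dist < best[0]:
                best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


def brute_force_otsu(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance over every gray level."""
    values = np.asarray(values, float).ravel()
    levels = np.unique(values)
    best_t, best_var = levels[0], -1.0
    for t in levels[:-1]:
        lo = values[values <= t]
        hi = values[values > t]
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


def brute_force_ring_assignment(
    labels: np.ndarray, ring_gap: float, ring_width: float
) -> np.ndarray:
    """Per-pixel nearest-nucleus ring assignment by direct enumeration.

    For every background pixel the distance to every labelled pixel is
    computed; pixels whose minimal distance falls in the ring band get the
    nearest nucleus's label (ties to the lower label).
    """
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    fg = np.argwhere(labels > 0)
    fg_labels = labels[labels > 0]
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            if labels[r, c]:
                continue
            d = np.hypot(fg[:, 0] - r, fg[:, 1] - c)
            dmin = d.min()
            if ring_gap < dmin <= ring_gap + ring_width:
                out[r, c] = fg_labels[d <= dmin + 1e-9].min()
    return out


def pearson_textbook(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the covariance definition, no library calls."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def binomial_ci(p: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson style via the binomial CDF) bounds on the
    observed fraction when the true rate is ``p`` over ``n`` trials."""
    from scipy.stats import binom

    lo = binom.ppf(alpha / 2, n, p) / n
    hi = binom.isf(alpha / 2, n, p) / n
    return float(lo), float(hi)
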