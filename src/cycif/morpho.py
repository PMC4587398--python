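"""Morphometric texture features from binarized single-channel images.

Implements the skeleton/branch/focus/enrichment feature family used for
single-cell texture profiling: per-cell binarization, topological skeleton
measurements with geometric step weighting, prominence-based focus counting
with a cluster score, and compartment enrichment ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.signal import convolve2d
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu, unsharp_mask
from skimage.morphology import skeletonize

__all__ = [
    "MorphConfig",
    "binarize_channel",
    "skeleton_features",
    "count_foci",
    "enrichment",
    "morph_feature_vector",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "skeleton_length",
    "n_branch_points",
    "n_endpoints",
    "n_foci",
    "focus_mean_intensity",
    "cluster_score",
    "enrichment_nuclear",
    "enrichment_ring",
)


@dataclass
class MorphConfig:
    """Which markers get morphometric features and with what parameters."""

    markers: list[str] = field(default_factory=list)
    features: tuple[str, ...] = FEATURE_NAMES
    binarize_method: str = "otsu"
    unsharp: bool = False
    min_distance: int = 3
    min_prominence: float | None = None  # None → 3 × MAD-based noise estimate
    focus_radius: float = 3.0


def binarize_channel(
    image: np.ndarray,
    mask: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    unsharp: bool = False,
) -> np.ndarray:
    """Threshold a channel inside a cell mask.

    Otsu is computed from masked pixels only; a constant region cannot be
    split and yields an all-background result.  Optional unsharp masking
    sharpens before thresholding.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask must match image shape")
    out = np.zeros(image.shape, dtype=bool)
    vals = image[mask]
    if vals.size == 0 or np.ptp(vals) == 0:
        return out
    if unsharp:
        image = unsharp_mask(image, radius=2, amount=1.0, preserve_range=True)
        vals = image[mask]
    if method == "otsu":
        t = threshold_otsu(vals)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = threshold
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    out[mask] = image[mask] > t
    return out


_ORTH = ((0, 1), (1, 0))
_DIAG = ((1, 1), (1, -1))


def skeleton_features(binary: np.ndarray) -> tuple[float, int, int]:
    """Skeletonize and measure (length, branch points, endpoints).

    Length counts skeleton adjacencies geometrically: 1 per orthogonal step,
    √2 per diagonal step.  Branch points are junctions: 8-connected clusters
    of skeleton pixels with >= 3 skeleton neighbours; endpoints have exactly
    1 neighbour.  Empty input gives zeros.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return 0.0, 0, 0
    skel = skeletonize(binary)
    if not skel.any():
        return 0.0, 0, 0
    s = skel.astype(np.uint8)
    length = 0.0
    for dr, dc in _ORTH:
        length += float(_adjacent_pairs(s, dr, dc))
    for dr, dc in _DIAG:
        length += np.sqrt(2.0) * float(_adjacent_pairs(s, dr, dc))
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    neighbours = convolve2d(s, kernel, mode="same")
    # pixels around a junction can all see >= 3 neighbours; cluster adjacent
    # candidates so one junction counts once
    candidates = skel & (neighbours >= 3)
    _, n_branch = ndi.label(candidates, ndi.generate_binary_structure(2, 2))
    n_end = int(np.sum(skel & (neighbours == 1)))
    return length, n_branch, n_end


def _adjacent_pairs(s: np.ndarray, dr: int, dc: int) -> int:
    """Count pixel pairs (p, p + (dr, dc)) that are both set."""
    h, w = s.shape
    a = s[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
    b = s[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)]
    return int(np.sum(a * b))


def _noise_sigma(vals: np.ndarray) -> float:
    med = np.median(vals)
    return 1.4826 * float(np.median(np.abs(vals - med)))


def count_foci(
    image: np.ndarray,
    mask: np.ndarray,
    min_prominence: float | None = None,
    min_distance: int = 3,
    focus_radius: float = 3.0,
) -> tuple[int, np.ndarray, float]:
    """Count punctate foci inside a mask and score signal clustering.

    Foci are local maxima exceeding the local background (median of masked
    pixels) by ``min_prominence`` (default 3 × a MAD-based noise estimate),
    separated by at least ``min_distance`` pixels.  ``cluster_score`` is the
    background-subtracted signal within discs of ``focus_radius`` around the
    foci divided by the total masked background-subtracted signal, clipped to
    [0, 1].
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = image[mask]
    if vals.size == 0 or np.ptp(vals) == 0:
        return 0, np.zeros((0, 2), dtype=int), 0.0
    background = float(np.median(vals))
    if min_prominence is None:
        min_prominence = 3.0 * max(_noise_sigma(vals), 1e-12)
    work = np.where(mask, image, -np.inf)
    peaks = peak_local_max(
        work,
        min_distance=min_distance,
        threshold_abs=background + min_prominence,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return 0, np.zeros((0, 2), dtype=int), 0.0
    signal = np.clip(image - background, 0.0, None)
    signal[~mask] = 0.0
    total = float(signal.sum())
    if total <= 0:
        return len(peaks), peaks, 0.0
    rr, cc = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    in_focus = np.zeros(image.shape, dtype=bool)
    for pr, pc in peaks:
        in_focus |= (rr - pr) ** 2 + (cc - pc) ** 2 <= focus_radius**2
    score = float(signal[in_focus].sum() / total)
    return len(peaks), peaks, float(np.clip(score, 0.0, 1.0))


def enrichment(
    image: np.ndarray,
    compartment_mask: np.ndarray,
    whole_cell_mask: np.ndarray,
    background: float = 0.0,
) -> float:
    """Mean compartment intensity over mean whole-cell intensity.

    Both means are background-subtracted; returns NaN (undefined, never
    zero) when the whole-cell mean signal is <= 0.  The compartment must be
    a subset of the whole cell.
    """
    comp = np.asarray(compartment_mask, bool)
    whole = np.asarray(whole_cell_mask, bool)
    if (comp & ~whole).any():
        raise ValueError("compartment mask must lie within the whole-cell mask")
    if not whole.any() or not comp.any():
        return np.nan
    image = np.asarray(image, float)
    whole_mean = image[whole].mean() - background
    if whole_mean <= 0:
        return np.nan
    comp_mean = image[comp].mean() - background
    return float(comp_mean / whole_mean)


def morph_feature_vector(
    table: pd.DataFrame,
    channel_images: dict[str, np.ndarray],
    labels: np.ndarray,
    rings: np.ndarray,
    config: MorphConfig,
) -> pd.DataFrame:
    """Append per-cell morphometric columns for each configured marker.

    Column order is deterministic: markers in config order, features in
    ``config.features`` order, named ``{marker}_{feature}``.  With no
    configured markers the table is returned unchanged.
    """
    if not config.markers:
        return table
    labels = np.asarray(labels)
    rings = np.asarray(rings)
    out = table.copy()
    objects = ndi.find_objects(labels)
    for marker in config.markers:
        image = np.asarray(channel_images[marker], dtype=float)
        cols: dict[str, list[float]] = {f: [] for f in config.features}
        for cid in out["cell_id"].astype(int):
            sl = objects[cid - 1] if cid - 1 < len(objects) else None
            if sl is None:
                for f in config.features:
                    cols[f].append(np.nan)
                continue
            # pad the crop so rings and focus discs fit
            pad = int(config.focus_radius + 4)
            r0 = max(sl[0].start - pad, 0)
            r1 = min(sl[0].stop + pad, labels.shape[0])
            c0 = max(sl[1].start - pad, 0)
            c1 = min(sl[1].stop + pad, labels.shape[1])
            crop = np.s_[r0:r1, c0:c1]
            nuc = labels[crop] == cid
            ring = rings[crop] == cid
            whole = nuc | ring
            img = image[crop]
            vals: dict[str, float] = {}
            if {"skeleton_length", "n_branch_points", "n_endpoints"} & set(config.features):
                binary = binarize_channel(
                    img, whole, method=config.binarize_method, unsharp=config.unsharp
                )
                ln, nb, ne = skeleton_features(binary)
                vals.update(skeleton_length=ln, n_branch_points=nb, n_endpoints=ne)
            if {"n_foci", "focus_mean_intensity", "cluster_score"} & set(config.features):
                n_foci, peaks, score = count_foci(
                    img,
                    whole,
                    min_prominence=config.min_prominence,
                    min_distance=config.min_distance,
                    focus_radius=config.focus_radius,
                )
                fmi = float(img[tuple(peaks.T)].mean()) if n_foci else np.nan
                vals.update(n_foci=n_foci, focus_mean_intensity=fmi, cluster_score=score)
            if "enrichment_nuclear" in config.features:
                vals["enrichment_nuclear"] = enrichment(img, nuc, whole)
            if "enrichment_ring" in config.features:
                vals["enrichment_ring"] = enrichment(img, ring, whole)
            for f in config.features:
                cols[f].append(vals.get(f, np.nan))
        for f in config.features:
            out[f"{marker}_{f}"] = cols[f]
    return out
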