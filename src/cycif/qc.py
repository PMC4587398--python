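"""Fluorophore-inactivation QC: bleach kinetics, residual checks, reproducibility.

The kinetic model is a single exponential with an asymptotic floor,
``I(t) = floor + (I0 - floor) * exp(-k t)`` — one decay rate per fluor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

__all__ = [
    "BleachKinetics",
    "InactivationReport",
    "fit_bleach_kinetics",
    "predict_required_bleach_time",
    "verify_inactivation",
    "cross_cycle_reproducibility",
    "estimate_background",
]


@dataclass
class BleachKinetics:
    k: float
    i0: float
    floor: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("decay constant k must be >= 0")

    def intensity(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.floor + (self.i0 - self.floor) * np.exp(-self.k * np.asarray(t, float))


@dataclass
class InactivationReport:
    median_residual: float
    passed: bool
    n_cells: int
    n_excluded: int
    threshold: float
    residuals: np.ndarray


def _model(t, k, i0, floor):
    return floor + (i0 - floor) * np.exp(-k * t)


def fit_bleach_kinetics(times: np.ndarray, intensities: np.ndarray) -> BleachKinetics:
    """Least-squares fit of the floored exponential decay.

    Requires >= 4 increasing, non-negative time points.  A constant signal
    fits exactly with ``k = 0``; non-convergence raises with the best
    iterate attached to the exception.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.ndim != 1 or y.shape != t.shape:
        raise ValueError("times and intensities must be matching 1D arrays")
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    if np.ptp(y) == 0:
        return BleachKinetics(k=0.0, i0=float(y[0]), floor=float(y[0]), r_squared=1.0)

    span = max(y.max() - y.min(), 1e-12)
    # crude initial rate from the half-decay point
    half = y.min() + span / 2.0
    below = np.nonzero(y <= half)[0]
    t_half = t[below[0]] if len(below) else t[-1]
    k0 = np.log(2.0) / max(t_half, (t[1] - t[0]))
    p0 = (k0, float(y[0]), float(y.min()))
    try:
        popt, _ = curve_fit(
            _model,
            t,
            y,
            p0=p0,
            bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"bleach-kinetics fit did not converge (p0={p0})") from exc
    resid = y - _model(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BleachKinetics(k=float(popt[0]), i0=float(popt[1]), floor=float(popt[2]), r_squared=r2)


def predict_required_bleach_time(kin: BleachKinetics, target_residual_fraction: float) -> float:
    """Time at which the residual fraction ``I(t)/I0`` reaches the target.

    Solves ``floor + (I0 - floor) exp(-k t) = target * I0`` for t; a target
    at or below the floor fraction is unachievable and raises.
    """
    if kin.k <= 0:
        raise ValueError("k must be > 0 to predict a bleach time")
    if kin.i0 <= 0:
        raise ValueError("I0 must be positive")
    floor_fraction = kin.floor / kin.i0
    if target_residual_fraction <= floor_fraction:
        raise ValueError(
            f"target residual {target_residual_fraction} not achievable: "
            f"floor fraction is {floor_fraction:.4g}"
        )
    if target_residual_fraction >= 1.0:
        return 0.0
    num = target_residual_fraction * kin.i0 - kin.floor
    den = kin.i0 - kin.floor
    return float(-np.log(num / den) / kin.k)


def estimate_background(image: np.ndarray, labels: np.ndarray, n_bins: int = 256) -> float:
    """Background level as the histogram mode of non-labelled pixels."""
    bg = np.asarray(image, float)[np.asarray(labels) == 0]
    if bg.size == 0:
        return 0.0
    if np.ptp(bg) == 0:
        return float(bg[0])
    hist, edges = np.histogram(bg, bins=n_bins)
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2.0)


def verify_inactivation(
    pre_image: np.ndarray,
    post_image: np.ndarray,
    labels: np.ndarray,
    background: float | None = None,
    threshold: float = 0.05,
) -> InactivationReport:
    """Check that a channel has been bleached to (near) background.

    Per-cell residual is ``(post - background) / (pre - background)`` over
    nuclear-mask means, clipped at 0.  Cells whose pre-bleach signal is
    indistinguishable from background are excluded from the median but
    counted.  The channel passes if the median residual <= ``threshold``.
    """
    labels = np.asarray(labels)
    if background is None:
        background = estimate_background(pre_image, labels)
    ids = np.arange(1, labels.max() + 1)
    if not len(ids):
        return InactivationReport(np.nan, True, 0, 0, threshold, np.array([]))
    pre_means = np.array(ndi.mean(np.asarray(pre_image, float), labels, ids))
    post_means = np.array(ndi.mean(np.asarray(post_image, float), labels, ids))
    pre_sig = pre_means - background
    post_sig = post_means - background
    # signal must clear background noise to define a ratio
    ok = pre_sig > max(1e-12, 0.05 * max(np.abs(pre_sig).max(), 1e-12))
    residuals = np.clip(post_sig[ok] / pre_sig[ok], 0.0, None)
    med = float(np.median(residuals)) if len(residuals) else np.nan
    return InactivationReport(
        median_residual=med,
        passed=bool(np.isnan(med) or med <= threshold),
        n_cells=int(len(residuals)),
        n_excluded=int((~ok).sum()),
        threshold=threshold,
        residuals=residuals,
    )


def cross_cycle_reproducibility(
    table: pd.DataFrame, marker_pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r and r² between repeat-stained marker columns.

    Missing values are skipped pairwise (complete cases only); fewer than 3
    complete cells or a zero-variance column yields an undefined (NaN) flag.
    """
    rows = []
    for col_a, col_b in marker_pairs:
        a = pd.to_numeric(table[col_a], errors="coerce")
        b = pd.to_numeric(table[col_b], errors="coerce")
        keep = a.notna() & b.notna()
        a, b = a[keep].to_numpy(), b[keep].to_numpy()
        defined = len(a) >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0
        r = pearsonr(a, b).statistic if defined else np.nan
        rows.append(
            {
                "col_a": col_a,
                "col_b": col_b,
                "r": r,
                "r_squared": r * r if defined else np.nan,
                "n": int(len(a)),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)
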