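"""Sub-pixel rigid registration of each cycle to the reference cycle.

Shifts are estimated on the shared DNA channel by phase correlation with
matrix-upsampled refinement; the same transform is then applied to every
channel of that cycle.  A :class:`RigidTransform` stores the *drift* of the
moving image relative to the reference, so ground-truth simulator drifts are
directly comparable; applying the transform undoes the drift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .imio import CycleStack

__all__ = [
    "RigidTransform",
    "estimate_shift",
    "estimate_rigid",
    "apply_transform",
    "register_stack",
]

log = logging.getLogger("cycif")


@dataclass(frozen=True)
class RigidTransform:
    """Estimated drift of a moving image relative to the reference frame.

    ``d_row``/``d_col`` are sub-pixel translations in pixels, ``theta`` a
    rotation in degrees about the image centre.  ``error_metric`` is the
    normalized cross-correlation between reference and aligned image,
    clipped to [0, 1].
    """

    d_row: float = 0.0
    d_col: float = 0.0
    theta: float = 0.0
    error_metric: float = 1.0

    def inverse(self) -> "RigidTransform":
        if self.theta == 0.0:
            return replace(self, d_row=-self.d_row, d_col=-self.d_col)
        t = np.deg2rad(-self.theta)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        d = -rot @ np.array([self.d_row, self.d_col])
        return RigidTransform(d[0], d[1], -self.theta, self.error_metric)

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.d_row, self.d_col))


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wr = np.hanning(shape[0])
    wc = np.hanning(shape[1])
    return np.outer(wr, wc)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / denom, 0.0, 1.0))


def _aligned_ncc(reference: np.ndarray, moving: np.ndarray, t: RigidTransform) -> float:
    aligned, mask = apply_transform(moving, t, return_mask=True)
    mask &= ndi.binary_erosion(mask, iterations=1) if mask.any() else mask
    if mask.sum() < 16:
        return 0.0
    return _ncc(reference[mask], aligned[mask])


def estimate_shift(
    reference: np.ndarray,
    moving: np.ndarray,
    upsample: int = 20,
    window: bool = True,
) -> RigidTransform:
    """Estimate the translation of ``moving`` relative to ``reference``.

    Phase correlation refined to a 1/``upsample`` pixel grid; with
    ``upsample=1`` the result is an exact integer shift.  A raised-cosine
    window suppresses wrap-around edge artefacts (real fields of view are
    not periodic).  Constant images carry no registration signal and raise.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must share a shape")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise ValueError("constant image: no registration signal")
    if window:
        w = _hann2d(reference.shape)
        ref_in = (reference - reference.mean()) * w
        mov_in = (moving - moving.mean()) * w
    else:
        ref_in, mov_in = reference, moving
    # pcc returns the correction to apply to `moving`, i.e. minus the drift
    shift, _, _ = phase_cross_correlation(
        ref_in, mov_in, upsample_factor=upsample, normalization=None
    )
    d_row, d_col = (-float(s) for s in shift)
    if upsample == 1:
        d_row, d_col = round(d_row), round(d_col)
    t = RigidTransform(d_row=d_row, d_col=d_col, theta=0.0)
    return replace(t, error_metric=_aligned_ncc(reference, moving, t))


def estimate_rigid(
    reference: np.ndarray,
    moving: np.ndarray,
    upsample: int = 20,
    angle_range: float = 5.0,
    coarse_step: float = 0.5,
    fine_step: float = 0.05,
) -> RigidTransform:
    """Estimate rotation + translation by angle search over shift estimates.

    A coarse sweep over ``[-angle_range, angle_range]`` degrees is refined
    around the best candidate at ``fine_step`` resolution; at each candidate
    angle the moving image is de-rotated about its centre and the residual
    translation estimated by :func:`estimate_shift`, keeping the angle/shift
    pair with maximal aligned correlation.
    """

    def candidate(theta: float) -> RigidTransform:
        derot = (
            moving
            if theta == 0.0
            else ndi.rotate(moving, -theta, reshape=False, order=1, mode="constant")
        )
        t = estimate_shift(reference, derot, upsample=upsample)
        # de-rotation is applied after the drift, so the residual shift seen
        # here is R(-theta) @ d; rotate it back into the forward model's frame
        a = np.deg2rad(theta)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        d = rot @ np.array([t.d_row, t.d_col])
        t = RigidTransform(float(d[0]), float(d[1]), theta)
        return replace(t, error_metric=_aligned_ncc(reference, moving, t))

    best = None
    for theta in np.arange(-angle_range, angle_range + 1e-9, coarse_step):
        c = candidate(float(theta))
        if best is None or c.error_metric > best.error_metric:
            best = c
    fine = np.arange(best.theta - coarse_step, best.theta + coarse_step + 1e-9, fine_step)
    for theta in fine:
        c = candidate(float(theta))
        if c.error_metric > best.error_metric:
            best = c
    if abs(best.theta) < fine_step / 2:
        best = replace(best, theta=0.0)
    return best


def apply_transform(
    image: np.ndarray,
    transform: RigidTransform,
    interpolation: str = "linear",
    fill: float = 0.0,
    return_mask: bool = False,
):
    """Resample ``image`` onto the reference frame (undo the stored drift).

    Out-of-frame pixels are filled with ``fill`` and flagged invalid in the
    optional mask.  ``interpolation`` is ``"linear"`` or ``"nearest"``;
    the identity transform returns the input bit-exactly in nearest mode.
    """
    order = {"linear": 1, "nearest": 0}[interpolation]
    image = np.asarray(image, dtype=float)
    if not all(np.isfinite([transform.d_row, transform.d_col, transform.theta])):
        raise ValueError("non-finite transform")
    if transform.d_row == 0 and transform.d_col == 0 and transform.theta == 0:
        out = image.copy()
        mask = np.ones(image.shape, dtype=bool)
        return (out, mask) if return_mask else out

    if transform.theta != 0.0:
        centre = (np.array(image.shape, float) - 1.0) / 2.0
        t = np.deg2rad(transform.theta)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        # forward model: y = R(x - c) + c + d, so the resampler pulls from
        # x = R @ (y - c) + c + d  (here rot == forward R since we feed
        # output coords through it): input = rot @ output + off
        off = centre + np.array([transform.d_row, transform.d_col]) - rot @ centre
        out = ndi.affine_transform(image, rot, offset=off, order=order, cval=fill)
        mask = (
            ndi.affine_transform(
                np.ones(image.shape), rot, offset=off, order=0, cval=0.0
            )
            > 0.5
        )
    else:
        shift = (-transform.d_row, -transform.d_col)
        out = ndi.shift(image, shift, order=order, cval=fill)
        mask = ndi.shift(np.ones(image.shape), shift, order=0, cval=0.0) > 0.5
    return (out, mask) if return_mask else out


def register_stack(
    stack: CycleStack,
    mode: str = "translation",
    upsample: int = 20,
    min_error_metric: float = 0.3,
) -> tuple[CycleStack, list[RigidTransform]]:
    """Align every cycle of ``stack`` to the reference cycle's DNA channel.

    The transform estimated from each cycle's DNA image is applied to all of
    that cycle's channels; the reference cycle is untouched.  Transforms with
    ``error_metric`` below ``min_error_metric`` are still applied but logged
    as QC warnings.
    """
    if mode not in ("translation", "rigid"):
        raise ValueError(f"unknown mode {mode!r}")
    ref = stack.dna(stack.reference_cycle)
    transforms: list[RigidTransform] = []
    new_cycles: list[dict[str, np.ndarray]] = []
    masks: list[np.ndarray | None] = []
    for c in range(stack.n_cycles):
        if c == stack.reference_cycle:
            t = RigidTransform()
            new_cycles.append({k: v.copy() for k, v in stack.cycles[c].items()})
            masks.append(np.ones(stack.shape, dtype=bool))
            transforms.append(t)
            continue
        moving = stack.dna(c)
        if mode == "translation":
            t = estimate_shift(ref, moving, upsample=upsample)
        else:
            t = estimate_rigid(ref, moving, upsample=upsample)
        if t.error_metric < min_error_metric:
            msg = (
                f"cycle {c + 1}: registration error_metric "
                f"{t.error_metric:.3f} below floor {min_error_metric}"
            )
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
        aligned = {}
        mask = None
        for name, img in stack.cycles[c].items():
            aligned[name], mask = apply_transform(img, t, return_mask=True)
        new_cycles.append(aligned)
        masks.append(mask)
        transforms.append(t)
    registered = CycleStack(
        cycles=new_cycles,
        reference_cycle=stack.reference_cycle,
        dna_channel=stack.dna_channel,
        valid=masks,
    )
    return registered, transforms
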