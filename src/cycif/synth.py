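"""Ground-truthed synthetic multi-cycle CycIF image generator.

Emulates the acquisition loop of a cyclic-immunofluorescence experiment:
fields of nuclei with perinuclear cytoplasm, per-cycle rigid drift,
incomplete fluorophore inactivation with exponential kinetics, stochastic
per-cycle cell loss, and log-normal marker intensities with a requested
pairwise correlation structure.  Every latent quantity is recorded in a
:class:`GroundTruth` so downstream stages have an exact oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .imio import CycleStack

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_experiment",
    "sample_correlated_intensities",
    "render_cells",
    "spot_integral",
    "residual_fraction",
    "write_experiment",
]

DNA = "DNA"

#: Gaussian edge taper of the flat-core nucleus profile, pixels.
EDGE_SIGMA = 1.5


@dataclass
class SimConfig:
    """Parameters of one simulated CycIF experiment.

    ``channels_per_cycle`` lists the *data* channel (marker) names for each
    cycle; the DNA channel is always rendered in addition.  Re-using a marker
    name in two cycles simulates repeat staining of the same antibody (the
    cell keeps one true intensity for that marker).
    """

    image_height: int = 256
    image_width: int = 256
    n_cycles: int = 3
    channels_per_cycle: Sequence[Sequence[str]] = ((), (), ())
    n_cells: int = 50
    nucleus_radius_range: tuple[float, float] = (4.0, 6.0)
    ring_width: float = 3.0
    drift_sigma: float = 2.0
    rotation_max: float = 0.0
    loss_rate_early: float = 0.03
    loss_rate_late: float = 0.01
    bleach_rate_k: float = 0.1
    bleach_time: float = 45.0
    residual_floor: float = 0.0
    marker_corr: np.ndarray | None = None
    marker_log_mean: float | np.ndarray = np.log(500.0)
    marker_log_sigma: float | np.ndarray = 0.4
    dna_intensity: float = 1000.0
    noise_sigma: float = 0.0
    background_level: float = 100.0
    cytoplasmic_markers: frozenset[str] = frozenset()
    allow_overlap: bool = False
    seed: int = 0

    @property
    def marker_names(self) -> list[str]:
        """Unique marker names in order of first appearance."""
        seen: list[str] = []
        for chans in self.channels_per_cycle:
            for name in chans:
                if name not in seen:
                    seen.append(name)
        return seen

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if len(self.channels_per_cycle) != self.n_cycles:
            raise ValueError(
                f"channels_per_cycle has {len(self.channels_per_cycle)} entries "
                f"for n_cycles={self.n_cycles}"
            )
        if any(DNA in chans for chans in self.channels_per_cycle):
            raise ValueError("the DNA channel is implicit; do not list it")
        for rate in (self.loss_rate_early, self.loss_rate_late):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"loss rate {rate} outside [0, 1]")
        lo, hi = self.nucleus_radius_range
        if not 0 < lo <= hi:
            raise ValueError("nucleus_radius_range must satisfy 0 < min <= max")
        if not 0.0 <= self.residual_floor <= 1.0:
            raise ValueError("residual_floor outside [0, 1]")
        if self.marker_corr is not None:
            _check_corr(np.asarray(self.marker_corr, float), len(self.marker_names))


@dataclass
class GroundTruth:
    """Simulator-side record of every latent value.

    Attributes
    ----------
    centres : (n_cells, 2) float array of (row, col) sub-pixel positions in
        the reference frame.
    intensities : (n_cells, n_markers) true per-marker mean intensities.
    present : (n_cells, n_cycles) boolean presence flags; once False at cycle
        c a cell stays False for all later cycles (detachment is
        irreversible).
    drifts : (n_cycles, 3) true (d_row, d_col, theta_degrees) of each cycle
        relative to the reference cycle; row 0 is the identity.
    """

    cell_ids: np.ndarray
    centres: np.ndarray
    radii: np.ndarray
    marker_names: list[str]
    intensities: np.ndarray
    dna_intensities: np.ndarray
    present: np.ndarray
    drifts: np.ndarray
    bleach_k: float
    carry_fraction: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


def _check_corr(corr: np.ndarray, n_markers: int) -> None:
    if corr.shape != (n_markers, n_markers):
        raise ValueError(
            f"marker_corr shape {corr.shape} does not match {n_markers} markers"
        )
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("marker_corr must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("marker_corr must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("marker_corr must be positive semi-definite")


def residual_fraction(k: float, bleach_time: float, floor: float) -> float:
    """Fraction of a fluor's signal that survives one inactivation step."""
    return floor + (1.0 - floor) * float(np.exp(-k * bleach_time))


def spot_integral(amplitude: float, radius: float, edge_sigma: float = EDGE_SIGMA) -> float:
    """Analytic integral of one rendered nucleus profile.

    The profile is ``A`` inside ``radius`` and ``A*exp(-(d-r)^2/(2s^2))``
    outside, so the integral is ``A*(pi r^2 + 2*pi*(s^2 + r*s*sqrt(pi/2)))``.
    """
    s = edge_sigma
    return amplitude * (
        np.pi * radius**2 + 2.0 * np.pi * (s**2 + radius * s * np.sqrt(np.pi / 2.0))
    )


def _profile(dist: np.ndarray, radius: float, edge_sigma: float) -> np.ndarray:
    out = np.exp(-np.clip(dist - radius, 0.0, None) ** 2 / (2.0 * edge_sigma**2))
    return out


def _ring_profile(
    dist: np.ndarray, radius: float, ring_width: float, edge_sigma: float
) -> np.ndarray:
    """Annular (cytoplasmic) profile: flat between r and r+w, tapered both ways."""
    inner = np.clip(radius - dist, 0.0, None)
    outer = np.clip(dist - (radius + ring_width), 0.0, None)
    d = np.maximum(inner, outer)
    return np.exp(-(d**2) / (2.0 * edge_sigma**2))


def render_cells(
    shape: tuple[int, int],
    centres: np.ndarray,
    radii: np.ndarray,
    amplitudes: np.ndarray,
    *,
    ring_width: float | None = None,
    edge_sigma: float = EDGE_SIGMA,
) -> np.ndarray:
    """Render cells onto a zero background.

    With ``ring_width=None`` each cell is a flat-core disc with a Gaussian
    edge (nuclear stain); otherwise an annulus from ``radius`` to
    ``radius + ring_width`` is rendered (cytoplasmic stain).
    """
    img = np.zeros(shape, dtype=np.float64)
    centres = np.atleast_2d(centres)
    pad = 4.0 * edge_sigma
    for (cr, cc), r, amp in zip(centres, np.ravel(radii), np.ravel(amplitudes)):
        extent = r + pad + (ring_width or 0.0)
        r0 = max(int(np.floor(cr - extent)), 0)
        r1 = min(int(np.ceil(cr + extent)) + 1, shape[0])
        c0 = max(int(np.floor(cc - extent)), 0)
        c1 = min(int(np.ceil(cc + extent)) + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc_ = np.meshgrid(
            np.arange(r0, r1, dtype=float), np.arange(c0, c1, dtype=float), indexing="ij"
        )
        dist = np.hypot(rr - cr, cc_ - cc)
        if ring_width is None:
            img[r0:r1, c0:c1] += amp * _profile(dist, r, edge_sigma)
        else:
            img[r0:r1, c0:c1] += amp * _ring_profile(dist, r, ring_width, edge_sigma)
    return img


def sample_correlated_intensities(
    n_cells: int,
    marker_corr: np.ndarray,
    means: float | np.ndarray,
    sigmas: float | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw strictly positive marker intensities with log-normal marginals.

    Log-intensities are multivariate normal with Pearson correlation
    ``marker_corr``, mean ``means`` and standard deviation ``sigmas``
    (both broadcast over markers).
    """
    corr = np.asarray(marker_corr, dtype=float)
    m = corr.shape[0]
    _check_corr(corr, m)
    mu = np.broadcast_to(np.asarray(means, float), (m,)).astype(float)
    sd = np.broadcast_to(np.asarray(sigmas, float), (m,)).astype(float)
    cov = corr * np.outer(sd, sd)
    logs = rng.multivariate_normal(mu, cov, size=n_cells, method="svd")
    return np.exp(logs)


def _place_centres(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample centres >= 2*max_radius apart (grid-accelerated)."""
    lo, hi = cfg.nucleus_radius_range
    min_sep = 0.0 if cfg.allow_overlap else 2.0 * hi
    margin = hi + cfg.ring_width + 2.0
    h, w = cfg.image_height, cfg.image_width
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("image too small for the configured nucleus size")
    cell = max(min_sep, 1.0)
    grid: dict[tuple[int, int], list[np.ndarray]] = {}
    centres: list[np.ndarray] = []
    max_attempts = max(2000, 300 * cfg.n_cells)
    attempts = 0
    while len(centres) < cfg.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {cfg.n_cells} cells with separation "
                f">= {min_sep:.1f}px in a {h}x{w} field "
                f"(placed {len(centres)} after {attempts} attempts)"
            )
        p = np.array(
            [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        )
        gi, gj = int(p[0] // cell), int(p[1] // cell)
        ok = True
        if min_sep > 0:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for q in grid.get((gi + di, gj + dj), ()):
                        if np.hypot(*(p - q)) < min_sep:
                            ok = False
                            break
        if ok:
            centres.append(p)
            grid.setdefault((gi, gj), []).append(p)
    return np.array(centres).reshape(cfg.n_cells, 2)


def simulate_experiment(config: SimConfig) -> tuple[CycleStack, GroundTruth]:
    """Run the virtual acquisition loop and return images plus ground truth.

    Per cycle: surviving cells are rendered at their drifted positions; the
    DNA channel is re-stained at full strength; each data channel carries the
    new stain plus the incompletely bleached residue of what occupied the
    same channel slot in the previous cycle; constant background and Gaussian
    camera noise are added last.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.nucleus_radius_range
    markers = config.marker_names
    n_markers = len(markers)

    if config.n_cells > 0:
        centres = _place_centres(config, rng)
        radii = rng.uniform(lo, hi, size=config.n_cells)
        if n_markers:
            corr = (
                np.asarray(config.marker_corr, float)
                if config.marker_corr is not None
                else np.eye(n_markers)
            )
            intensities = sample_correlated_intensities(
                config.n_cells, corr, config.marker_log_mean,
                config.marker_log_sigma, rng,
            )
        else:
            intensities = np.zeros((config.n_cells, 0))
        dna = config.dna_intensity * rng.uniform(0.9, 1.1, size=config.n_cells)
    else:
        centres = np.zeros((0, 2))
        radii = np.zeros(0)
        intensities = np.zeros((0, n_markers))
        dna = np.zeros(0)

    # presence: irreversible Bernoulli detachment on each cycle transition
    present = np.ones((config.n_cells, config.n_cycles), dtype=bool)
    for c in range(1, config.n_cycles):
        rate = config.loss_rate_early if c <= 2 else config.loss_rate_late
        detach = rng.random(config.n_cells) < rate
        present[:, c] = present[:, c - 1] & ~detach

    drifts = np.zeros((config.n_cycles, 3))
    for c in range(1, config.n_cycles):
        drifts[c, :2] = rng.normal(0.0, config.drift_sigma, size=2)
        if config.rotation_max > 0:
            drifts[c, 2] = rng.uniform(-config.rotation_max, config.rotation_max)

    carry = residual_fraction(
        config.bleach_rate_k, config.bleach_time, config.residual_floor
    )
    n_slots = max((len(ch) for ch in config.channels_per_cycle), default=0)
    # per-cell residual amplitude sitting in each data-channel slot
    slot_resid = np.zeros((config.n_cells, n_slots))

    shape = (config.image_height, config.image_width)
    centre_px = (np.array(shape, float) - 1.0) / 2.0
    cycles: list[dict[str, np.ndarray]] = []
    for c in range(config.n_cycles):
        alive = present[:, c]
        dr, dc, theta = drifts[c]
        pos = centres.copy()
        if theta != 0.0 and len(pos):
            t = np.deg2rad(theta)
            rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            pos = (pos - centre_px) @ rot.T + centre_px
        pos = pos + np.array([dr, dc])

        images: dict[str, np.ndarray] = {}
        images[DNA] = render_cells(shape, pos[alive], radii[alive], dna[alive])
        slot_new = np.zeros_like(slot_resid)
        for j, marker in enumerate(config.channels_per_cycle[c]):
            mi = markers.index(marker)
            amp = intensities[:, mi] + slot_resid[:, j] * carry
            slot_new[:, j] = amp
            is_ring = marker in config.cytoplasmic_markers
            images[marker] = render_cells(
                shape, pos[alive], radii[alive], amp[alive],
                ring_width=config.ring_width if is_ring else None,
            )
        # slots with no new stain this cycle still decay toward nothing
        for j in range(n_slots):
            if j >= len(config.channels_per_cycle[c]):
                slot_new[:, j] = slot_resid[:, j] * carry
        slot_resid = slot_new

        for name, img in images.items():
            img += config.background_level
            if config.noise_sigma > 0:
                img += rng.normal(0.0, config.noise_sigma, size=shape)
            images[name] = img
        cycles.append(images)

    stack = CycleStack(cycles=cycles, reference_cycle=0, dna_channel=DNA)
    truth = GroundTruth(
        cell_ids=np.arange(1, config.n_cells + 1),
        centres=centres,
        radii=radii,
        marker_names=markers,
        intensities=intensities,
        dna_intensities=dna,
        present=present,
        drifts=drifts,
        bleach_k=config.bleach_rate_k,
        carry_fraction=carry,
    )
    return stack, truth


def write_experiment(stack: CycleStack, truth: GroundTruth, config: SimConfig,
                     out_dir) -> "Path":
    """Write per-cycle multi-page TIFFs plus a YAML ground-truth sidecar.

    Returns the path of the manifest YAML that :func:`cycif.imio.read_stack`
    accepts.
    """
    from pathlib import Path

    from .imio import write_stack

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = write_stack(stack, out_dir)

    def plain(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, np.generic):
            return v.item()
        if isinstance(v, frozenset):
            return sorted(v)
        if isinstance(v, (tuple, list)):
            return [plain(x) for x in v]
        if isinstance(v, dict):
            return {k: plain(x) for k, x in v.items()}
        return v

    sidecar = {
        "config": {k: plain(v) for k, v in dataclasses.asdict(config).items()},
        "ground_truth": plain(truth.to_dict()),
    }
    with open(out_dir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return manifest_path
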