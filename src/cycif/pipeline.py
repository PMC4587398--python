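"""End-to-end orchestration: registered stack → segmentation → cell table.

Thin glue over the stage modules, shared by the CLI ``run-all`` command and
by tests that exercise the whole path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
import scipy.ndimage as ndi
import numpy as np

from .imio import CycleStack
from .quantify import assemble_cell_table, cell_loss_profile, match_cells, measure_cells
from .register import RigidTransform, register_stack
from .segment import SegmentationParams, make_ring_rois, segment_nuclei

log = logging.getLogger("cycif")


@dataclass
class PipelineResult:
    table: pd.DataFrame
    transforms: list[RigidTransform]
    labels: np.ndarray
    rings: np.ndarray
    loss_profile: pd.DataFrame


def run_pipeline(
    stack: CycleStack,
    seg_params: SegmentationParams | None = None,
    registration_mode: str = "translation",
    max_match_dist: float = 5.0,
) -> PipelineResult:
    """Register, segment on the reference cycle, measure and assemble.

    Cells are defined by the reference cycle's DNA segmentation; each later
    cycle is segmented independently only for tracking, while intensities
    are measured for every cycle through the tracked per-cycle labels.
    """
    seg_params = seg_params or SegmentationParams()
    registered, transforms = register_stack(stack, mode=registration_mode)

    label_images = [
        segment_nuclei(registered.dna(c), seg_params) for c in range(registered.n_cycles)
    ]
    ring_images = [
        make_ring_rois(lbl, seg_params.ring_width, seg_params.ring_gap)
        for lbl in label_images
    ]
    measurements = []
    for c in range(registered.n_cycles):
        channels = {
            name: img
            for name, img in registered.cycles[c].items()
            if name != registered.dna_channel
        }
        channels[registered.dna_channel] = registered.dna(c)
        measurements.append(
            measure_cells(
                label_images[c], ring_images[c], channels, valid_mask=registered.valid[c]
            )
        )
    matchings = [
        match_cells(label_images[c], label_images[c + 1], max_dist=max_match_dist)
        for c in range(registered.n_cycles - 1)
    ]
    ref = registered.reference_cycle
    ref_labels = label_images[ref]
    ids = np.arange(1, ref_labels.max() + 1)
    centroids = {}
    areas = {}
    if len(ids):
        coms = ndi.center_of_mass(ref_labels > 0, ref_labels, ids)
        counts = np.bincount(ref_labels.ravel(), minlength=ids.max() + 1)
        centroids = {int(i): (float(r), float(c)) for i, (r, c) in zip(ids, coms)}
        areas = {int(i): float(counts[i]) for i in ids}
    table = assemble_cell_table(measurements, matchings, centroids, areas)
    loss = cell_loss_profile(registered, seg_params, max_dist=max_match_dist)
    return PipelineResult(
        table=table,
        transforms=transforms,
        labels=ref_labels,
        rings=ring_images[ref],
        loss_profile=loss,
    )
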