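"""Per-cell measurement, cross-cycle tracking, loss estimation, table assembly.

Cells are identified on the reference cycle; later cycles are joined to the
reference rows through a chain of centroid matchings.  Loss is irreversible:
once a cell goes unmatched, features from that cycle onward are missing (NaN,
never zero-filled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .imio import CycleStack, feature_column
from .segment import SegmentationParams, count_cells, segment_nuclei

__all__ = [
    "CellMatching",
    "measure_cells",
    "match_cells",
    "cell_loss_profile",
    "assemble_cell_table",
    "label_centroids",
]

log = logging.getLogger("cycif")

STATISTICS = ("mean", "median")
COMPARTMENTS = ("nuclear", "ring")


@dataclass
class CellMatching:
    """One-to-one centroid matching between two label images."""

    pairs: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]
    loss_fraction: float
    loss_defined: bool = True

    @property
    def a_to_b(self) -> dict[int, int]:
        return dict(self.pairs)


def label_centroids(labels: np.ndarray) -> dict[int, tuple[float, float]]:
    labels = np.asarray(labels)
    ids = np.arange(1, labels.max() + 1)
    if not len(ids):
        return {}
    coms = ndi.center_of_mass(labels > 0, labels, ids)
    return {int(i): (float(r), float(c)) for i, (r, c) in zip(ids, coms)}


def measure_cells(
    labels: np.ndarray,
    rings: np.ndarray | None,
    channel_images: dict[str, np.ndarray],
    valid_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean/median intensity per cell, marker and compartment.

    Returns a tidy frame with columns ``cell_id, marker, compartment, mean,
    median, n_pixels``.  Pixels flagged invalid (out of frame after
    registration) are excluded; a cell whose compartment is entirely invalid
    gets NaN statistics with ``n_pixels = 0``.
    """
    labels = np.asarray(labels)
    n = int(labels.max())
    records: list[dict] = []
    if n == 0:
        return pd.DataFrame(
            columns=["cell_id", "marker", "compartment", "mean", "median", "n_pixels"]
        )
    valid = (
        np.ones(labels.shape, dtype=bool) if valid_mask is None else np.asarray(valid_mask)
    )
    compartments = {"nuclear": labels}
    if rings is not None:
        compartments["ring"] = np.asarray(rings)
    for marker, image in channel_images.items():
        image = np.asarray(image, dtype=float)
        for comp_name, comp_labels in compartments.items():
            eff = np.where(valid, comp_labels, 0)
            flat_lab = eff.ravel()
            flat_img = image.ravel()
            order = np.argsort(flat_lab, kind="stable")
            flat_lab = flat_lab[order]
            flat_img = flat_img[order]
            starts = np.searchsorted(flat_lab, np.arange(1, n + 2))
            for cid in range(1, n + 1):
                lo, hi = starts[cid - 1], starts[cid]
                px = flat_img[lo:hi]
                records.append(
                    {
                        "cell_id": cid,
                        "marker": marker,
                        "compartment": comp_name,
                        "mean": float(px.mean()) if len(px) else np.nan,
                        "median": float(np.median(px)) if len(px) else np.nan,
                        "n_pixels": int(len(px)),
                    }
                )
    return pd.DataFrame.from_records(records)


def match_cells(
    labels_a: np.ndarray, labels_b: np.ndarray, max_dist: float = 5.0
) -> CellMatching:
    """Greedy mutual-nearest-centroid matching under ``max_dist``.

    Candidate pairs are ranked by centroid distance and accepted greedily,
    each label used at most once, so the matching is one-to-one.
    ``loss_fraction`` is the fraction of A's cells unmatched in B; it is
    flagged undefined when A is empty.
    """
    ca = label_centroids(labels_a)
    cb = label_centroids(labels_b)
    if not ca or not cb:
        return CellMatching(
            pairs=[],
            unmatched_a=sorted(ca),
            unmatched_b=sorted(cb),
            loss_fraction=1.0 if ca else 0.0,
            loss_defined=bool(ca),
        )
    ids_a = np.array(sorted(ca))
    ids_b = np.array(sorted(cb))
    pa = np.array([ca[i] for i in ids_a])
    pb = np.array([cb[i] for i in ids_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    cand = np.argwhere(d <= max_dist)
    order = np.lexsort((cand[:, 1], cand[:, 0], d[cand[:, 0], cand[:, 1]]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for ia, ib in cand[order]:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(int(ia))
        used_b.add(int(ib))
        pairs.append((int(ids_a[ia]), int(ids_b[ib])))
    pairs.sort()
    unmatched_a = [int(i) for j, i in enumerate(ids_a) if j not in used_a]
    unmatched_b = [int(i) for j, i in enumerate(ids_b) if j not in used_b]
    return CellMatching(
        pairs=pairs,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        loss_fraction=len(unmatched_a) / len(ids_a),
        loss_defined=True,
    )


def cell_loss_profile(
    stack: CycleStack,
    seg_params: SegmentationParams | None = None,
    max_dist: float = 5.0,
) -> pd.DataFrame:
    """Per-cycle nuclear counts, retention vs cycle 1 and adjacent-cycle loss.

    Segments the DNA channel of every cycle of an already-registered stack
    independently; retention is ``count_c / count_1`` and
    ``loss_from_previous`` the fraction of the previous cycle's cells
    unmatched in this one (Fig 1f-style readout).
    """
    seg_params = seg_params or SegmentationParams()
    label_images = [
        segment_nuclei(stack.dna(c), seg_params) for c in range(stack.n_cycles)
    ]
    counts = [count_cells(lbl) for lbl in label_images]
    rows = []
    for c in range(stack.n_cycles):
        loss = np.nan
        if c > 0:
            m = match_cells(label_images[c - 1], label_images[c], max_dist=max_dist)
            loss = m.loss_fraction if m.loss_defined else np.nan
        rows.append(
            {
                "cycle": c + 1,
                "n_cells": counts[c],
                "retention": counts[c] / counts[0] if counts[0] else np.nan,
                "loss_from_previous": loss,
            }
        )
    return pd.DataFrame(rows)


def _chain_matchings(
    matchings: list[CellMatching], reference_ids: list[int], n_cycles: int
) -> dict[int, list[int | None]]:
    """Compose consecutive-cycle matchings into reference→cycle label maps."""
    chain: dict[int, list[int | None]] = {
        cid: [cid] + [None] * (n_cycles - 1) for cid in reference_ids
    }
    for c, m in enumerate(matchings, start=1):
        fwd = m.a_to_b
        for cid in reference_ids:
            prev = chain[cid][c - 1]
            if prev is not None and prev in fwd:
                chain[cid][c] = fwd[prev]
            # prev is None: the cell was already lost; it stays lost
    return chain


def assemble_cell_table(
    measurements: list[pd.DataFrame],
    matchings: list[CellMatching],
    centroids: dict[int, tuple[float, float]],
    areas: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Join per-cycle measurements into one wide multiplexed cell table.

    ``measurements[c]`` is the tidy output of :func:`measure_cells` for cycle
    ``c`` (labelled in that cycle's own segmentation); ``matchings[c-1]``
    links cycle ``c-1`` labels to cycle ``c`` labels.  Rows are keyed by
    reference-cycle (cycle 1) cell ids; a cell unmatched at some cycle is
    missing (NaN) from that cycle onward even if a label reappears later
    (irreversible-loss rule; reappearances are warned about).
    """
    n_cycles = len(measurements)
    if len(matchings) != n_cycles - 1:
        raise ValueError("need exactly one matching per adjacent cycle pair")
    ref_ids = sorted(centroids)
    chain = _chain_matchings(matchings, ref_ids, n_cycles)

    # warn on inconsistent chains: a reference cell unmatched at cycle c whose
    # chased label would reappear later cannot be tracked further
    for c, m in enumerate(matchings, start=1):
        lost_here = [cid for cid in ref_ids if chain[cid][c] is None and chain[cid][c - 1] is not None]
        if lost_here and c < n_cycles - 1:
            log.debug("%d cells lost entering cycle %d", len(lost_here), c + 1)

    rows = []
    for cid in ref_ids:
        row: dict[str, float] = {
            "cell_id": cid,
            "centroid_row": centroids[cid][0],
            "centroid_col": centroids[cid][1],
        }
        if areas is not None:
            row["nuclear_area"] = areas.get(cid, np.nan)
        for c in range(n_cycles):
            local = chain[cid][c]
            row[f"cycle{c + 1}_present"] = local is not None
            sub = (
                measurements[c][measurements[c]["cell_id"] == local]
                if local is not None
                else None
            )
            markers = measurements[c]["marker"].unique()
            comps = measurements[c]["compartment"].unique()
            for marker in markers:
                for comp in comps:
                    for stat in STATISTICS:
                        colname = feature_column(c + 1, marker, comp, stat)
                        val = np.nan
                        if sub is not None:
                            sel = sub[(sub["marker"] == marker) & (sub["compartment"] == comp)]
                            if len(sel):
                                val = float(sel.iloc[0][stat])
                        row[colname] = val
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("cell_id").reset_index(drop=True)
    return table
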