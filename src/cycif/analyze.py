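"""Downstream single-cell analysis: correlations, clustering, gating, export.

The embedding/trajectory algorithms themselves (viSNE, Wanderlust) are
external tools; this module prepares and documents their inputs, and
implements the in-house statistics: pairwise Pearson r², average-linkage
hierarchical clustering, three-marker cell-cycle gating, and per-column
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import pearsonr

__all__ = [
    "ClusterResult",
    "GateConfig",
    "pairwise_r2",
    "hcluster",
    "gate_cell_cycle",
    "normalize_for_export",
    "export_for_embedding",
    "load_supplementary_table",
    "find_ps6_columns",
    "select_condition",
    "ps6_correlation",
    "WANDERLUST_DEFAULTS",
]

#: Downstream trajectory-tool defaults recorded in export manifests.
WANDERLUST_DEFAULTS = {
    "L": 30,
    "K": 5,
    "n_landmarks": 20,
    "n_graphs": 25,
    "metric": "cosine",
}


@dataclass
class ClusterResult:
    """Average-linkage merge tree plus a flat cut and a display ordering."""

    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)
    labels: np.ndarray  # flat cluster labels, 1..n_clusters
    order: np.ndarray  # leaf order for heatmap display
    n_dropped: int  # rows removed for missing values

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class GateConfig:
    """Thresholds and column names for three-marker cell-cycle gating.

    Thresholds are either absolute values or, via ``percentile_thresholds``,
    percentiles of the observed column distribution.
    """

    prb_column: str = "p-Rb"
    dna_column: str = "DNA"
    ki67_column: str = "Ki-67"
    prb_threshold: float = 0.0
    dna_threshold: float = 0.0
    ki67_threshold: float = 0.0
    percentile_thresholds: bool = False


def pairwise_r2(
    table: pd.DataFrame, col_a: str, col_b: str, transform: str = "identity"
) -> tuple[float, float, int]:
    """Pearson r and r² between two columns on complete cases.

    ``transform`` is ``"identity"`` or ``"log"`` (natural log, applied to
    both columns; non-positive values are dropped).  Returns
    ``(r, r_squared, n)``; undefined correlations (fewer than 3 complete
    cases or zero variance) are NaN-flagged.
    """
    a = pd.to_numeric(table[col_a], errors="coerce")
    b = pd.to_numeric(table[col_b], errors="coerce")
    keep = a.notna() & b.notna()
    if transform == "log":
        keep &= (a > 0) & (b > 0)
    x = a[keep].to_numpy(float)
    y = b[keep].to_numpy(float)
    if transform == "log":
        x, y = np.log(x), np.log(y)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    r = float(pearsonr(x, y).statistic)
    return r, r * r, n


def hcluster(table: pd.DataFrame, columns: list[str], n_clusters: int) -> ClusterResult:
    """Agglomerative clustering, Euclidean distance, average linkage (UPGMA).

    Rows with missing values in ``columns`` are dropped (and counted in the
    result).  Flat labels come from cutting the tree at ``n_clusters``;
    ``order`` is the dendrogram leaf order for heatmap display.
    """
    data = table[columns].apply(pd.to_numeric, errors="coerce")
    complete = data.notna().all(axis=1)
    x = data[complete].to_numpy(float)
    n_dropped = int((~complete).sum())
    n = len(x)
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} complete rows")
    if n == 1:
        return ClusterResult(
            linkage=np.zeros((0, 4)),
            labels=np.array([1]),
            order=np.array([0]),
            n_dropped=n_dropped,
        )
    z = linkage(x, method="average", metric="euclidean")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return ClusterResult(
        linkage=z, labels=labels, order=np.asarray(leaves_list(z)), n_dropped=n_dropped
    )


def gate_cell_cycle(
    table: pd.DataFrame, config: GateConfig
) -> tuple[pd.Series, dict[str, float]]:
    """Label cells as G0 / G1-S / G2 from p-Rb, DNA and Ki-67 thresholds.

    Gates: p-Rb low & Ki-67 low → G0; p-Rb high & DNA low → G1/S; p-Rb high
    & DNA high → G2.  The remaining combination (p-Rb low, Ki-67 high) is
    reported as ``unassigned``; cells with missing gate markers are
    ``unlabelled``.  Returned fractions are over assigned phases and sum
    to 1 when any cell is assigned.
    """
    for col in (config.prb_column, config.dna_column, config.ki67_column):
        if col not in table.columns:
            raise KeyError(f"gate marker column {col!r} not in table")
    prb = pd.to_numeric(table[config.prb_column], errors="coerce")
    dna = pd.to_numeric(table[config.dna_column], errors="coerce")
    ki67 = pd.to_numeric(table[config.ki67_column], errors="coerce")

    def thr(series: pd.Series, value: float) -> float:
        if config.percentile_thresholds:
            return float(np.nanpercentile(series, value))
        return value

    t_prb = thr(prb, config.prb_threshold)
    t_dna = thr(dna, config.dna_threshold)
    t_ki = thr(ki67, config.ki67_threshold)

    labels = pd.Series("unlabelled", index=table.index, dtype=object)
    complete = prb.notna() & dna.notna() & ki67.notna()
    hi_prb = prb > t_prb
    labels[complete & ~hi_prb & (ki67 <= t_ki)] = "G0"
    labels[complete & ~hi_prb & (ki67 > t_ki)] = "unassigned"
    labels[complete & hi_prb & (dna <= t_dna)] = "G1/S"
    labels[complete & hi_prb & (dna > t_dna)] = "G2"

    phases = ("G0", "G1/S", "G2")
    n_assigned = int(labels.isin(phases).sum())
    fractions = {
        p: (float((labels == p).sum()) / n_assigned if n_assigned else np.nan)
        for p in phases
    }
    return labels, fractions


def normalize_for_export(table: pd.DataFrame, method: str = "arcsinh",
                         cofactor: float = 150.0,
                         percentile_range: tuple[float, float] = (0.0, 100.0),
                         columns: list[str] | None = None) -> pd.DataFrame:
    """Per-column normalization before export to cytometry-style tools.

    ``arcsinh``: x → arcsinh(x / cofactor).  ``percentile``: min–max scaling
    between the given percentiles, clipped to [0, 1]; a constant column maps
    to 0.  Non-finite input values are rejected with their locations.  The
    chosen method is recorded in ``table.attrs["normalization"]``.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])]
    for col in columns:
        vals = out[col].to_numpy(float)
        bad = ~np.isfinite(vals) & ~np.isnan(vals)
        if bad.any():
            raise ValueError(
                f"non-finite values in column {col!r} at rows {np.flatnonzero(bad).tolist()}"
            )
        if method == "arcsinh":
            out[col] = np.arcsinh(vals / cofactor)
        elif method == "percentile":
            lo, hi = np.nanpercentile(vals, percentile_range)
            span = hi - lo
            out[col] = (
                np.zeros_like(vals)
                if span == 0
                else np.clip((vals - lo) / span, 0.0, 1.0)
            )
        else:
            raise ValueError(f"unknown normalization method {method!r}")
    out.attrs["normalization"] = {
        "method": method,
        "cofactor": cofactor if method == "arcsinh" else None,
        "percentile_range": list(percentile_range) if method == "percentile" else None,
        "columns": list(columns),
    }
    return out


def export_for_embedding(
    table: pd.DataFrame,
    path,
    condition_column: str,
    columns: list[str] | None = None,
) -> list[Path]:
    """Write one numeric CSV per condition plus a YAML manifest.

    The manifest records the per-condition files and the published default
    parameters of the downstream trajectory tool (documentation metadata,
    not executed here).  Exported columns must be complete (no NaN).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c != condition_column and pd.api.types.is_numeric_dtype(table[c])
        ]
    if table[columns].isna().any().any():
        raise ValueError("exported columns must be complete (no missing values)")
    files: list[Path] = []
    entries = []
    for cond, sub in table.groupby(condition_column, sort=True):
        safe = str(cond).replace("/", "_").replace(" ", "_")
        f = path / f"condition_{safe}.csv"
        sub[columns].to_csv(f, index=False)
        files.append(f)
        entries.append({"condition": str(cond), "file": f.name, "n_cells": int(len(sub))})
    manifest = {
        "columns": list(columns),
        "conditions": entries,
        "wanderlust_defaults": dict(WANDERLUST_DEFAULTS),
        "normalization": table.attrs.get("normalization"),
    }
    mpath = path / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return files + [mpath]


def load_supplementary_table(
    path,
    condition_column: str | None = None,
) -> pd.DataFrame:
    """Load a deposited single-cell intensity table (CSV or Excel).

    Multi-sheet Excel workbooks are concatenated with the sheet name as the
    ``condition`` column.  A flat file must either contain an explicit
    condition column (named by ``condition_column``, or auto-detected from
    common names) — the per-cell condition labelling is read from the file,
    never guessed from row order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        if len(sheets) > 1:
            frames = []
            for name, frame in sheets.items():
                frame = frame.copy()
                frame["condition"] = name
                frames.append(frame)
            return pd.concat(frames, ignore_index=True)
        table = next(iter(sheets.values()))
    else:
        table = pd.read_csv(path)
    if condition_column is not None:
        if condition_column not in table.columns:
            raise KeyError(
                f"condition column {condition_column!r} not found in {path.name}; "
                f"available: {list(table.columns)}"
            )
        table = table.rename(columns={condition_column: "condition"})
        return table
    for cand in ("condition", "Condition", "treatment", "Treatment", "dose", "Dose"):
        if cand in table.columns:
            return table.rename(columns={cand: "condition"})
    raise ValueError(
        f"{path.name} has no recognizable condition column; pass "
        "condition_column= explicitly (the per-cell condition labelling must "
        "come from the file itself)"
    )


def _canon(name: str) -> str:
    return "".join(ch for ch in str(name).lower() if ch.isalnum())


def find_ps6_columns(table: pd.DataFrame) -> tuple[str, str]:
    """Locate the S6-phosphosite columns (S235/236 and S240/244) by name.

    Matching is insensitive to case, punctuation and spacing, so
    ``p-S6(S235/236)``, ``pS6_235_236`` etc. all resolve.
    """
    col_235 = col_240 = None
    for col in table.columns:
        c = _canon(col)
        if "s6" in c and "235" in c:
            col_235 = col
        elif "s6" in c and "240" in c:
            col_240 = col
    if col_235 is None or col_240 is None:
        raise KeyError(
            "could not locate both S6-phosphosite columns; available: "
            f"{list(table.columns)}"
        )
    return col_235, col_240


def select_condition(table: pd.DataFrame, pattern: str) -> pd.DataFrame:
    """Rows whose ``condition`` value contains ``pattern`` (canonicalized)."""
    if "condition" not in table.columns:
        raise KeyError("table has no 'condition' column")
    pat = _canon(pattern)
    keep = table["condition"].map(lambda v: pat in _canon(v))
    sub = table[keep]
    if not len(sub):
        raise ValueError(
            f"no rows match condition pattern {pattern!r}; "
            f"conditions present: {sorted(table['condition'].astype(str).unique())}"
        )
    return sub


def ps6_correlation(table: pd.DataFrame, condition_pattern: str) -> tuple[float, int]:
    """Squared Pearson correlation of the two S6 phosphosites in a condition."""
    sub = select_condition(table, condition_pattern)
    col_a, col_b = find_ps6_columns(sub)
    _, r2, n = pairwise_r2(sub, col_a, col_b)
    return r2, n
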