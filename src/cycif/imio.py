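"""Image-stack and table I/O, experiment layout, configuration.

File conventions: one multi-page TIFF per cycle with the DNA page first and
the channel name stored in each page's description; a YAML manifest binding
cycles, paths and channel names; cell tables as RFC-4180 CSV printed at full
float precision so that write→read round-trips are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "CycleStack",
    "ExperimentManifest",
    "read_stack",
    "write_stack",
    "write_cell_table",
    "read_cell_table",
    "feature_column",
]

log = logging.getLogger("cycif")

DEFAULT_DNA_CHANNEL = "DNA"


@dataclass
class CycleStack:
    """Raw or registered image data for one experiment.

    ``cycles[c]`` maps channel name → 2D float image; every cycle contains
    the DNA channel and all images share one shape.  ``valid`` optionally
    carries a boolean in-frame mask per cycle (set by registration).
    """

    cycles: list[dict[str, np.ndarray]]
    reference_cycle: int = 0
    dna_channel: str = DEFAULT_DNA_CHANNEL
    valid: list[np.ndarray | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cycles:
            raise ValueError("CycleStack needs at least one cycle")
        shape = None
        for c, channels in enumerate(self.cycles):
            if self.dna_channel not in channels:
                raise ValueError(
                    f"cycle {c + 1} is missing the DNA channel "
                    f"{self.dna_channel!r}"
                )
            for name, img in channels.items():
                img = np.asarray(img)
                if img.ndim != 2:
                    raise ValueError(f"channel {name!r} in cycle {c + 1} is not 2D")
                if shape is None:
                    shape = img.shape
                elif img.shape != shape:
                    raise ValueError(
                        f"shape mismatch: channel {name!r} in cycle {c + 1} is "
                        f"{img.shape}, expected {shape}"
                    )
        if not self.valid:
            self.valid = [None] * len(self.cycles)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.cycles[0].values())).shape

    def channel_names(self, cycle: int) -> list[str]:
        names = list(self.cycles[cycle])
        names.remove(self.dna_channel)
        return [self.dna_channel] + names

    def dna(self, cycle: int) -> np.ndarray:
        return self.cycles[cycle][self.dna_channel]


@dataclass
class ExperimentManifest:
    """Per-cycle file layout of an experiment on disk.

    ``cycles`` is an ordered list of ``{"path": ..., "channels": [...]}``
    where channel order matches TIFF page order; optional per-cycle
    ``prestain_path`` entries point at background images taken before
    staining.  Marker names must be unique across the experiment (the DNA
    channel, re-imaged every cycle, is exempt).
    """

    cycles: list[dict]
    dna_channel: str = DEFAULT_DNA_CHANNEL
    reference_cycle: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c, entry in enumerate(self.cycles):
            for name in entry["channels"]:
                if name == self.dna_channel:
                    continue
                if name in seen:
                    raise ValueError(
                        f"marker name {name!r} appears in more than one cycle; "
                        "marker names must be unique across the experiment "
                        "(suffix repeat stains, e.g. 'pERK.c2')"
                    )
                seen.add(name)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = Path(path).parent
        cycles = []
        for entry in doc["cycles"]:
            entry = dict(entry)
            entry["path"] = str((base / entry["path"]).resolve())
            if entry.get("prestain_path"):
                entry["prestain_path"] = str((base / entry["prestain_path"]).resolve())
            cycles.append(entry)
        return cls(
            cycles=cycles,
            dna_channel=doc.get("dna_channel", DEFAULT_DNA_CHANNEL),
            reference_cycle=doc.get("reference_cycle", 0),
        )

    def to_yaml(self, path) -> None:
        base = Path(path).parent
        doc = {
            "dna_channel": self.dna_channel,
            "reference_cycle": self.reference_cycle,
            "cycles": [
                {
                    **entry,
                    "path": str(Path(entry["path"]).relative_to(base))
                    if Path(entry["path"]).is_absolute()
                    else entry["path"],
                }
                for entry in self.cycles
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def read_stack(manifest: ExperimentManifest | str | Path) -> CycleStack:
    """Load a :class:`CycleStack` from a manifest (object or YAML path).

    Images are converted to float64; integer pixel values are preserved
    exactly.  A cycle whose file lacks the DNA channel raises a hard error
    naming the cycle.
    """
    if not isinstance(manifest, ExperimentManifest):
        manifest = ExperimentManifest.from_yaml(manifest)
    cycles = []
    for c, entry in enumerate(manifest.cycles):
        path = Path(entry["path"])
        if not path.exists():
            raise FileNotFoundError(f"cycle {c + 1}: image file {path} not found")
        with tifffile.TiffFile(path) as tif:
            pages = [page.asarray() for page in tif.pages]
        names = list(entry["channels"])
        if len(names) != len(pages):
            raise ValueError(
                f"cycle {c + 1}: {len(pages)} TIFF pages but {len(names)} "
                "channel names in manifest"
            )
        if manifest.dna_channel not in names:
            raise ValueError(
                f"cycle {c + 1} has no DNA channel {manifest.dna_channel!r}"
            )
        cycles.append(
            {name: np.asarray(page, dtype=np.float64) for name, page in zip(names, pages)}
        )
    return CycleStack(
        cycles=cycles,
        reference_cycle=manifest.reference_cycle,
        dna_channel=manifest.dna_channel,
    )


def write_stack(stack: CycleStack, out_dir, stem: str = "cycle") -> Path:
    """Write one multi-page TIFF per cycle (DNA page first) plus a manifest.

    Returns the manifest YAML path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for c in range(stack.n_cycles):
        names = stack.channel_names(c)
        path = out_dir / f"{stem}{c + 1:02d}.tif"
        with tifffile.TiffWriter(path) as tif:
            for name in names:
                tif.write(
                    stack.cycles[c][name].astype(np.float32),
                    description=name,
                    contiguous=False,
                )
        entries.append({"path": path.name, "channels": names})
    manifest = ExperimentManifest(
        cycles=[{**e, "path": str(out_dir / e["path"])} for e in entries],
        dna_channel=stack.dna_channel,
        reference_cycle=stack.reference_cycle,
    )
    manifest_path = out_dir / "manifest.yaml"
    manifest.to_yaml(manifest_path)
    return manifest_path


def feature_column(cycle: int, marker: str, compartment: str, statistic: str) -> str:
    """Canonical feature-column name: ``cycle{c}_{marker}_{compartment}_{stat}``."""
    return f"cycle{cycle}_{marker}_{compartment}_{statistic}"


def write_cell_table(table: pd.DataFrame, path) -> Path:
    """Write a cell table as CSV with a lossless numeric round-trip.

    One row per cell; duplicate column names are rejected.  An explicitly
    empty table yields a header-only CSV.
    """
    if table.columns.duplicated().any():
        dups = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column names: {dups}")
    path = Path(path)
    # repr-based float formatting round-trips exactly through read_csv
    table.to_csv(path, index=False)
    return path


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
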