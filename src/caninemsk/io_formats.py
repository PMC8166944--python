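"""Readers and writers for the motion, load, model, and result formats.

Two tab-delimited text formats from the motion-capture ecosystem are
supported: storage tables (STO/MOT: free-form header terminated by an
``endheader`` sentinel, column-label row, time in the first column) and TRC
marker files (DataRate/NumFrames header, one X/Y/Z column triple per
marker).  Model configurations are YAML with a versioned schema.  All
writers are deterministic: fixed float formatting at 8 significant digits,
no timestamps, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .model_core import ModelConfig, assemble_model

__all__ = [
    "StorageTable",
    "FormatError",
    "read_storage",
    "write_storage",
    "read_trc",
    "read_model_yaml",
    "write_run_manifest",
]

FLOAT_FMT = "{:.8g}"


class FormatError(ValueError):
    """Malformed storage/TRC file."""


@dataclass
class StorageTable:
    """Tab-delimited numeric table with a keyed header.

    The first column is time (or stride percentage) and must be strictly
    increasing.  ``in_degrees`` records the header flag; angle data are
    converted to radians on load and back on save.
    """

    name: str
    columns: list[str]
    data: np.ndarray  # (n_rows, n_cols) including time column
    in_degrees: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.columns):
            raise FormatError("column count does not match labels")
        t = self.data[:, 0]
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise FormatError("first (time) column must be strictly increasing")

    def column(self, label: str) -> np.ndarray:
        return self.data[:, self.columns.index(label)]


def read_storage(path, angles_to_radians: bool = True) -> StorageTable:
    """Parse an STO/MOT-style storage table.

    The header runs to the ``endheader`` sentinel; ``inDegrees=yes`` makes
    non-time columns angles in degrees, converted to radians on load when
    ``angles_to_radians`` (the flag is kept so saving converts back).
    """
    with open(path, "r", newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    meta: dict = {}
    name = ""
    end = None
    for i, ln in enumerate(lines):
        if ln.strip() == "endheader":
            end = i
            break
        if "=" in ln:
            k, v = ln.split("=", 1)
            meta[k.strip()] = v.strip()
        elif ln.strip() and i == 0:
            name = ln.strip()
    if end is None:
        raise FormatError(f"{path}: no 'endheader' sentinel found")
    labels_line = end + 1
    while labels_line < len(lines) and not lines[labels_line].strip():
        labels_line += 1
    columns = lines[labels_line].split("\t")
    rows = []
    for ln_no, ln in enumerate(lines[labels_line + 1 :], start=labels_line + 2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != len(columns):
            raise FormatError(
                f"{path}:{ln_no}: ragged row ({len(parts)} fields, expected {len(columns)})"
            )
        rows.append([float(p) for p in parts])
    in_degrees = str(meta.get("inDegrees", "no")).lower() == "yes"
    data = np.array(rows, dtype=float)
    if in_degrees and angles_to_radians and data.size:
        data[:, 1:] = np.deg2rad(data[:, 1:])
    return StorageTable(
        name=name or meta.get("name", ""), columns=columns, data=data,
        in_degrees=in_degrees, metadata=meta,
    )


def write_storage(table: StorageTable, path) -> None:
    """Emit a storage table; inverse of :func:`read_storage` at 8 significant
    digits."""
    data = table.data.copy()
    if table.in_degrees and data.size:
        data[:, 1:] = np.rad2deg(data[:, 1:])
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{table.name}\n")
        fh.write(f"nRows={data.shape[0]}\n")
        fh.write(f"nColumns={data.shape[1]}\n")
        fh.write(f"inDegrees={'yes' if table.in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(table.columns) + "\n")
        for row in data:
            fh.write("\t".join(FLOAT_FMT.format(v) for v in row) + "\n")


def read_trc(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Parse a TRC marker file into (time, {marker: (n, 3) positions}).

    Positions are converted to metres when the Units field says mm.  Blank
    cells are flagged as gaps with NaN, never silently zeroed.
    """
    with open(path, "r", newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    if len(lines) < 6:
        raise FormatError(f"{path}: truncated TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    n_markers = int(header.get("NumMarkers", 0))
    units = header.get("Units", "mm")
    scale = 1e-3 if units.lower() == "mm" else 1.0
    marker_names = [m for m in lines[3].split("\t")[2:] if m]
    if len(marker_names) != n_markers:
        raise FormatError(
            f"{path}: NumMarkers={n_markers} but {len(marker_names)} marker labels"
        )
    time = []
    cols: list[list[list[float]]] = [[] for _ in marker_names]
    for ln in lines[5:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        time.append(float(parts[1]))
        for k in range(n_markers):
            cell = parts[2 + 3 * k : 5 + 3 * k]
            if len(cell) < 3 or any(c.strip() == "" for c in cell):
                cols[k].append([np.nan, np.nan, np.nan])
            else:
                cols[k].append([float(c) * scale for c in cell])
    markers = {name: np.array(cols[k]) for k, name in enumerate(marker_names)}
    return np.array(time), markers


def read_model_yaml(path) -> ModelConfig:
    """Load and validate a model configuration file."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return assemble_model(spec)


def write_run_manifest(path, inputs: dict, parameters: dict) -> None:
    """JSON run manifest: inputs, parameters, and tool version — enough to
    re-run the command that produced a result."""
    from . import __version__

    manifest = {"tool": "caninemsk", "version": __version__,
                "inputs": inputs, "parameters": parameters}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
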