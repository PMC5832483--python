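"""Plain-text grid export/import.

Each grid is a tab-separated matrix (one row per raster line, ``nan`` for
masked cells) plus a JSON sidecar with the physical metadata (pitches in
μm, origin, isotope label, unit).  The matrix doubles as the height-map
export: row/column position plus value is exactly the 3-D surface data.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .exceptions import SchemaError
from .gridding import IntensityGrid


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", label) or "grid"


def save_grid(grid: IntensityGrid, directory: str | Path, name: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = _safe_name(name or grid.isotope_label)
    matrix_path = directory / f"{name}.tsv"
    vals = np.where(grid.mask, grid.values, np.nan)
    np.savetxt(matrix_path, vals, delimiter="\t", fmt="%.10g")
    meta = {
        "isotope_label": grid.isotope_label,
        "unit": grid.unit,
        "pitch_x_um": grid.pitch_x,
        "pitch_y_um": grid.pitch_y,
        "origin_um": list(grid.origin),
        "shape": list(grid.shape),
        "row_files": None if grid.row_files is None else grid.row_files.tolist(),
    }
    (directory / f"{name}.meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return matrix_path


def load_grid(matrix_path: str | Path) -> IntensityGrid:
    matrix_path = Path(matrix_path)
    meta_path = matrix_path.with_suffix("").with_suffix(".meta.json")
    if not meta_path.exists():
        meta_path = matrix_path.parent / (matrix_path.stem + ".meta.json")
    if not meta_path.exists():
        raise SchemaError(f"missing sidecar metadata for {matrix_path}")
    meta = json.loads(meta_path.read_text())
    values = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    row_files = meta.get("row_files")
    return IntensityGrid(
        values=values,
        mask=np.isfinite(values),
        pitch_x=meta["pitch_x_um"],
        pitch_y=meta["pitch_y_um"],
        isotope_label=meta["isotope_label"],
        unit=meta["unit"],
        origin=tuple(meta["origin_um"]),
        row_files=None if row_files is None else np.asarray(row_files, dtype=int),
    )


def save_grids(grids: dict[str, IntensityGrid], directory: str | Path) -> dict[str, Path]:
    return {label: save_grid(g, directory, label) for label, g in grids.items()}


def load_grids(directory: str | Path) -> dict[str, IntensityGrid]:
    directory = Path(directory)
    out: dict[str, IntensityGrid] = {}
    for matrix_path in sorted(directory.glob("*.tsv")):
        g = load_grid(matrix_path)
        out[g.isotope_label] = g
    if not out:
        raise SchemaError(f"no grid exports (*.tsv with sidecars) found in {directory}")
    return out
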