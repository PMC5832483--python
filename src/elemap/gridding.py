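"""Conversion of segmented time profiles into X-Y intensity grids.

Each raster line becomes one grid row; a reading's along-scan position is
its elapsed time within the line times the raster rate, so the horizontal
pixel pitch is ``raster_rate * reading_interval`` and the vertical pitch is
the line spacing.  Rows of unequal length are padded with masked cells, not
truncated, so interrupted acquisitions still load.  Shape corrections
(per-line / per-file horizontal offsets plus a linear shear) are realized as
fractional-pixel row translations with within-row linear interpolation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import GeometryError, SchemaError
from .segmentation import LineSegmentation
from .tra import TRASeries


@dataclass(frozen=True)
class RasterGeometry:
    """Physical geometry of the raster scan.

    ``raster_rate`` in μm/s, ``line_spacing`` in μm.  ``scan_direction``
    is ``same`` (every line scanned left→right) or ``serpentine``
    (odd-numbered rows reversed).  ``origin`` is the sample-frame position of
    the first pixel center, in μm.
    """

    raster_rate: float
    line_spacing: float
    scan_direction: str = "same"
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.raster_rate <= 0:
            raise SchemaError("raster_rate must be > 0")
        if self.line_spacing <= 0:
            raise SchemaError("line_spacing must be > 0")
        if self.scan_direction not in ("same", "serpentine"):
            raise SchemaError("scan_direction must be 'same' or 'serpentine'")


@dataclass
class IntensityGrid:
    """One reconstructed 2-D map (rows = raster lines).

    ``values`` is ``[n_lines, n_cols]``; ``mask`` is True where a cell holds
    a real reading.  Column j's center is ``origin[0] + j*pitch_x`` and row
    k's center is ``origin[1] + k*pitch_y`` (μm, pixel-center convention).
    ``unit`` tags the physical meaning (``CPS``, ``ratio``, ``wt%``, ...).
    """

    values: np.ndarray
    pitch_x: float
    pitch_y: float
    isotope_label: str = ""
    unit: str = "CPS"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    origin: tuple[float, float] = (0.0, 0.0)
    row_files: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("grid values must be 2-D")
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise SchemaError("pitches must be > 0")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise SchemaError("mask shape must match values")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise SchemaError("unmasked cells must be finite")
        if self.row_files is not None:
            self.row_files = np.asarray(self.row_files, dtype=int)
            if self.row_files.shape != (self.values.shape[0],):
                raise SchemaError("row_files must have one entry per row")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[1]) * self.pitch_x

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[0]) * self.pitch_y

    def unmasked(self) -> np.ndarray:
        """1-D array of the valid cell values."""
        return self.values[self.mask]

    def same_geometry(self, other: "IntensityGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pitch_x, other.pitch_x)
            and np.isclose(self.pitch_y, other.pitch_y)
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class ShapeCorrection:
    """Horizontal shifts applied per row, in μm.

    Row k is shifted by
    ``per_line_offset[k] + per_file_offset[file(k)] + shear * k``.
    ``per_line_offset`` may be a scalar or an array with one entry per line;
    ``per_file_offset`` maps source-file ids to offsets.
    """

    per_line_offset: float | np.ndarray = 0.0
    per_file_offset: dict[int, float] = field(default_factory=dict)
    shear: float = 0.0

    def row_shifts(self, n_rows: int, row_files: np.ndarray | None) -> np.ndarray:
        shifts = np.broadcast_to(
            np.asarray(self.per_line_offset, dtype=float), (n_rows,)
        ).copy()
        if self.per_file_offset:
            if row_files is None:
                raise SchemaError("per_file_offset given but grid has no row_files")
            for k in range(n_rows):
                shifts[k] += self.per_file_offset.get(int(row_files[k]), 0.0)
        shifts += self.shear * np.arange(n_rows)
        if not np.all(np.isfinite(shifts)):
            raise SchemaError("shape-correction offsets must be finite")
        return shifts


def build_grids(
    series: TRASeries, seg: LineSegmentation, geom: RasterGeometry
) -> dict[str, IntensityGrid]:
    """Reconstruct one :class:`IntensityGrid` per isotope.

    Row k holds line k's readings in time order; the horizontal pitch is the
    raster rate times the median intra-line reading interval.  Rows shorter
    than the longest line are padded with masked cells; a line with zero
    readings becomes a fully masked row (with a warning).
    """
    line_idx = seg.line_index_of(series.times)
    rows: list[np.ndarray] = []
    row_files = np.zeros(seg.n_lines, dtype=int)
    intra_diffs: list[np.ndarray] = []
    for k in range(seg.n_lines):
        sel = np.nonzero(line_idx == k)[0]
        rows.append(sel)
        if sel.size == 0:
            warnings.warn(f"line {k} contains no readings; row fully masked", stacklevel=2)
        else:
            row_files[k] = int(np.bincount(series.source_files[sel]).argmax())
            if sel.size > 1:
                intra_diffs.append(np.diff(series.times[sel]))
    if not intra_diffs:
        raise GeometryError("no line contains two readings; cannot set pixel pitch")
    reading_interval = float(np.median(np.concatenate(intra_diffs)))
    pitch_x = geom.raster_rate * reading_interval
    n_cols = max(sel.size for sel in rows)

    grids: dict[str, IntensityGrid] = {}
    for j, label in enumerate(series.isotope_labels):
        values = np.full((seg.n_lines, n_cols), np.nan)
        mask = np.zeros((seg.n_lines, n_cols), dtype=bool)
        for k, sel in enumerate(rows):
            row = series.intensities[sel, j]
            if geom.scan_direction == "serpentine" and k % 2 == 1:
                row = row[::-1]
            values[k, : row.size] = row
            mask[k, : row.size] = True
        grids[label] = IntensityGrid(
            values=values,
            mask=mask,
            pitch_x=pitch_x,
            pitch_y=geom.line_spacing,
            isotope_label=label,
            unit="CPS",
            origin=geom.origin,
            row_files=row_files.copy(),
        )
    return grids


def _shift_row(values: np.ndarray, mask: np.ndarray, shift_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Translate one row by ``shift_px`` pixels (positive = content moves
    toward higher x) using linear interpolation; cells that would sample
    outside the row, or through a masked cell, are masked."""
    n = values.size
    src = np.arange(n) - shift_px
    lo = np.floor(src).astype(int)
    frac = src - lo
    hi = lo + 1
    # exact integer shifts need only one source cell
    exact = frac < 1e-12
    hi = np.where(exact, lo, hi)
    inside = (lo >= 0) & (hi <= n - 1)
    lo_c = np.clip(lo, 0, n - 1)
    hi_c = np.clip(hi, 0, n - 1)
    ok = inside & mask[lo_c] & mask[hi_c]
    out = np.full(n, np.nan)
    out[ok] = (1 - frac[ok]) * values[lo_c[ok]] + frac[ok] * values[hi_c[ok]]
    return out, ok


def apply_shape_correction(
    grids: dict[str, IntensityGrid] | IntensityGrid, corr: ShapeCorrection
) -> dict[str, IntensityGrid] | IntensityGrid:
    """Apply horizontal row shifts to one grid or a set of grids.

    Shifts are in μm; fractional-pixel translations use within-row linear
    interpolation and newly exposed cells are masked.  A zero correction is
    the identity.
    """
    if isinstance(grids, IntensityGrid):
        return _apply_one(grids, corr)
    return {label: _apply_one(g, corr) for label, g in grids.items()}


def _apply_one(grid: IntensityGrid, corr: ShapeCorrection) -> IntensityGrid:
    shifts_um = corr.row_shifts(grid.shape[0], grid.row_files)
    if np.allclose(shifts_um, 0.0):
        return replace(grid, values=grid.values.copy(), mask=grid.mask.copy())
    values = np.full_like(grid.values, np.nan)
    mask = np.zeros_like(grid.mask)
    for k in range(grid.shape[0]):
        values[k], mask[k] = _shift_row(
            grid.values[k], grid.mask[k], shifts_um[k] / grid.pitch_x
        )
    return replace(grid, values=values, mask=mask)


def running_average(grid: IntensityGrid, half_width: int) -> IntensityGrid:
    """Smooth along the scan direction with a ±``half_width`` moving mean.

    Each unmasked cell is replaced by the mean of the unmasked cells within
    ``half_width`` columns of it in the same row; the mask is unchanged.
    Spike suppression along the raster direction trades off horizontal
    resolution.
    """
    if half_width < 0:
        raise SchemaError("half_width must be >= 0")
    if half_width == 0:
        return replace(grid, values=grid.values.copy(), mask=grid.mask.copy())
    v = np.where(grid.mask, grid.values, 0.0)
    m = grid.mask.astype(float)
    kernel = np.ones(2 * half_width + 1)
    out = np.full_like(grid.values, np.nan)
    for k in range(grid.shape[0]):
        num = np.convolve(v[k], kernel, mode="same")
        den = np.convolve(m[k], kernel, mode="same")
        row_ok = grid.mask[k] & (den > 0)
        out[k, row_ok] = num[row_ok] / den[row_ok]
    return replace(grid, values=out, mask=grid.mask.copy())
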