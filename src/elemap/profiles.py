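"""Bilinear evaluation at arbitrary sample coordinates and line profiles.

Grid readings are spatially discrete, so intensity between pixel centers is
estimated from the four surrounding measured points P1..P4: first two linear
interpolations along the rows bounding the query point,

    I_A = I1 + (I2 - I1) * dX / (X2 - X1)        (lower row)
    I_B = I3 + (I4 - I3) * dX / (X2 - X1)        (upper row)

then one along the column,

    I_T = I_A + (I_B - I_A) * dY / (Y2 - Y1),

where (dX, dY) is the query's offset from P1.  Queries outside the
pixel-center bounding box, or touching a masked corner, are rejected — no
extrapolation and no clamping, because a clamped endpoint would silently
distort profile statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MaskedDataError, RangeError, SchemaError
from .gridding import IntensityGrid


@dataclass(frozen=True)
class ProfileQuery:
    """A straight profile from ``start`` to ``end`` (μm) with ``n_samples``
    equally spaced points, endpoints included.  ``n_samples=None`` picks
    one sample per finer-pitch step along the segment."""

    start: tuple[float, float]
    end: tuple[float, float]
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if tuple(self.start) == tuple(self.end):
            raise SchemaError("profile start and end must differ")
        if self.n_samples is not None and self.n_samples < 2:
            raise SchemaError("n_samples must be >= 2")


def _locate(grid: IntensityGrid, x: float, y: float) -> tuple[int, int, float, float]:
    """Return (row, col, dx_frac, dy_frac) of the cell whose lower-left
    pixel-center corner P1 encloses (x, y)."""
    nx = grid.shape[1]
    ny = grid.shape[0]
    fx = (x - grid.origin[0]) / grid.pitch_x
    fy = (y - grid.origin[1]) / grid.pitch_y
    if not (0.0 <= fx <= nx - 1 and 0.0 <= fy <= ny - 1):
        raise RangeError(
            f"point ({x:g}, {y:g}) μm lies outside the pixel-center bounding box"
        )
    j = min(int(np.floor(fx)), nx - 2) if nx > 1 else 0
    k = min(int(np.floor(fy)), ny - 2) if ny > 1 else 0
    return k, j, fx - j, fy - k


def interpolate_at(grid: IntensityGrid, point: tuple[float, float]) -> float:
    """Bilinearly interpolated intensity at a sample-frame point (μm).

    At a grid node (dX = dY = 0) this returns the stored value exactly; the
    result is always bounded by the four corner intensities.  A masked
    corner raises :class:`MaskedDataError`; a point outside the pixel-center
    hull raises :class:`RangeError`.
    """
    x, y = float(point[0]), float(point[1])
    if grid.shape[0] < 2 or grid.shape[1] < 2:
        raise SchemaError("interpolation needs at least a 2x2 grid")
    k, j, dx, dy = _locate(grid, x, y)
    corners = grid.mask[k : k + 2, j : j + 2]
    if not corners.all():
        raise MaskedDataError(
            f"point ({x:g}, {y:g}) μm has a masked corner; no extrapolation is done"
        )
    i1 = grid.values[k, j]
    i2 = grid.values[k, j + 1]
    i3 = grid.values[k + 1, j]
    i4 = grid.values[k + 1, j + 1]
    # closed form of the two row interpolations followed by one column step
    return float(
        i1 * (1 - dx) * (1 - dy) + i2 * dx * (1 - dy) + i3 * (1 - dx) * dy + i4 * dx * dy
    )


def line_profile(
    grid: IntensityGrid, query: ProfileQuery
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a straight profile; returns (distances μm, intensities).

    Samples falling on masked corners are reported as NaN gaps rather than
    aborting the whole profile.  Both endpoints must lie inside the
    pixel-center bounding box.
    """
    x0, y0 = query.start
    x1, y1 = query.end
    length = float(np.hypot(x1 - x0, y1 - y0))
    n = query.n_samples
    if n is None:
        n = int(np.ceil(length / min(grid.pitch_x, grid.pitch_y))) + 1
        n = max(n, 2)
    t = np.linspace(0.0, 1.0, n)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    out = np.empty(n)
    for i in range(n):
        try:
            out[i] = interpolate_at(grid, (xs[i], ys[i]))
        except MaskedDataError:
            out[i] = np.nan
    return t * length, out
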