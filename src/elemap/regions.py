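"""Polygonal regions of interest and per-ROI isotope correlation.

Membership is decided per pixel center (even-odd rule, boundary points
inside) and intersected with the grid's validity mask, so ROI statistics
are plain unweighted statistics over real readings.  Rectangles are just
4-vertex polygons — one code path.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .exceptions import GeometryError
from .gridding import IntensityGrid


@dataclass(frozen=True)
class ROIPolygon:
    """A labelled, simple (non-self-intersecting) polygon in μm."""

    label: str
    vertices: tuple[tuple[float, float], ...]
    color: str = ""

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError(f"ROI {self.label!r}: need at least 3 vertices")
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(
                f"ROI {self.label!r}: polygon must be non-self-intersecting with area > 0"
            )

    @property
    def shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    @classmethod
    def rectangle(
        cls, label: str, x0: float, y0: float, x1: float, y1: float, color: str = ""
    ) -> "ROIPolygon":
        xa, xb = sorted((x0, x1))
        ya, yb = sorted((y0, y1))
        return cls(label, ((xa, ya), (xb, ya), (xb, yb), (xa, yb)), color)


def polygon_mask(grid: IntensityGrid, roi: ROIPolygon) -> np.ndarray:
    """Boolean membership mask: cell centers covered by the polygon
    (boundary inclusive) and valid in the grid.  An ROI too small to catch
    any center yields an empty mask with a warning."""
    xs = grid.x_centers
    ys = grid.y_centers
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.intersects_xy(roi.shapely, gx.ravel(), gy.ravel()).reshape(grid.shape)
    member = inside & grid.mask
    if not member.any():
        warnings.warn(f"ROI {roi.label!r} contains no valid pixel centers", stacklevel=2)
    return member


@dataclass
class ROICorrelation:
    label: str
    n: int
    r: float  # NaN when undefined (zero variance in either channel)
    a_values: np.ndarray
    b_values: np.ndarray
    degenerate: bool = False


@dataclass
class CorrelationResult:
    """Per-ROI paired intensity samples and Pearson r for two isotopes."""

    isotope_a: str
    isotope_b: str
    rois: list[ROICorrelation] = field(default_factory=list)

    def summary(self) -> list[tuple[str, int, float]]:
        return [(roi.label, roi.n, roi.r) for roi in self.rois]


def correlate(
    grid_a: IntensityGrid, grid_b: IntensityGrid, rois: list[ROIPolygon]
) -> CorrelationResult:
    """Gather paired (a, b) values over each ROI and compute Pearson r.

    ROIs with fewer than two member pixels are skipped with a warning; an
    ROI where either channel is constant is reported with r = NaN and
    flagged degenerate.  Overlapping ROIs each receive the shared pixels.
    """
    if not grid_a.same_geometry(grid_b):
        raise GeometryError("correlation operands must share geometry")
    result = CorrelationResult(isotope_a=grid_a.isotope_label, isotope_b=grid_b.isotope_label)
    for roi in rois:
        member = polygon_mask(grid_a, roi) & grid_b.mask
        n = int(member.sum())
        if n < 2:
            warnings.warn(
                f"ROI {roi.label!r}: fewer than 2 member pixels; skipped", stacklevel=2
            )
            continue
        a = grid_a.values[member]
        b = grid_b.values[member]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            result.rois.append(
                ROICorrelation(roi.label, n, float("nan"), a, b, degenerate=True)
            )
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        result.rois.append(ROICorrelation(roi.label, n, r, a, b))
    return result


def read_roi_file(path) -> list[ROIPolygon]:
    """Read ROIs from a vertex-list table: whitespace/comma rows of
    ``label x y``; consecutive rows with the same label form one polygon."""
    from pathlib import Path

    rows: list[tuple[str, float, float]] = []
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    use_comma = bool(lines) and "," in lines[0]
    for line in lines:
        parts = [p.strip() for p in (line.split(",") if use_comma else line.split())]
        if len(parts) != 3:
            raise GeometryError(f"ROI file row must be 'label x y': {line!r}")
        rows.append((parts[0], float(parts[1]), float(parts[2])))
    polys: list[ROIPolygon] = []
    current: list[tuple[float, float]] = []
    current_label: str | None = None
    for label, x, y in rows:
        if label != current_label and current:
            polys.append(ROIPolygon(current_label, tuple(current)))
            current = []
        current_label = label
        current.append((x, y))
    if current:
        polys.append(ROIPolygon(current_label, tuple(current)))
    return polys
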