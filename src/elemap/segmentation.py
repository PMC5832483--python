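"""Splitting a continuous raster record into line and gas-blank windows.

A raster acquisition alternates laser-on line scans with laser-off gas
blanks.  Separation points are placed at the midpoint of each blank gap;
each line's signal window and the surrounding blank windows are derived from
them, so adjusting a separation point moves the downstream windows with it.
The blank windows provide the per-line background estimate that is
subtracted from the line signal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import AdjustmentError, BackgroundError, CoverageError, SchemaError
from .tra import TRASeries


@dataclass(frozen=True)
class ScanTiming:
    """Timing parameters of a raster run.

    ``line_interval`` is the start-to-start period; the laser-off gap between
    lines is ``line_interval - line_duration``.  ``blank_margin`` (seconds)
    is excluded on each side of every blank window to keep washout tails out
    of the background estimate; ``None`` selects the default of 20% of the
    gap duration per side.
    """

    first_line_start: float
    line_duration: float
    line_interval: float
    n_lines: int
    blank_margin: float | None = None

    def __post_init__(self) -> None:
        if self.line_duration <= 0:
            raise SchemaError("line_duration must be > 0")
        if self.line_interval <= self.line_duration:
            raise SchemaError("line_interval must exceed line_duration")
        if self.n_lines < 1:
            raise SchemaError("n_lines must be >= 1")
        m = self.resolved_margin
        if m < 0 or 2 * m >= self.gap:
            raise SchemaError("blank_margin must satisfy 0 <= 2*margin < gap")

    @property
    def gap(self) -> float:
        return self.line_interval - self.line_duration

    @property
    def resolved_margin(self) -> float:
        return 0.2 * self.gap if self.blank_margin is None else self.blank_margin


@dataclass(frozen=True)
class LineSegmentation:
    """Separation points plus the windows derived from them.

    ``separation_points`` has ``n_lines + 1`` strictly increasing timestamps,
    one in the middle of each blank gap (including the gaps before the first
    and after the last line).  Line k's signal window starts ``gap/2`` after
    separation point k and lasts ``line_duration``; blank window k occupies
    the gap around separation point k, shrunk by ``margin`` on each side.
    Line windows select readings half-open, ``start <= t < end``.
    """

    separation_points: np.ndarray
    line_duration: float
    gap: float
    margin: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "separation_points", np.asarray(self.separation_points, dtype=float)
        )
        if self.separation_points.ndim != 1 or self.separation_points.size < 2:
            raise SchemaError("need at least 2 separation points (1 line)")
        if np.any(np.diff(self.separation_points) <= 0):
            raise SchemaError("separation points must be strictly increasing")

    @property
    def n_lines(self) -> int:
        return self.separation_points.size - 1

    @property
    def line_windows(self) -> np.ndarray:
        """[n_lines, 2] array of (start, end) seconds per line."""
        starts = self.separation_points[:-1] + self.gap / 2
        return np.column_stack([starts, starts + self.line_duration])

    @property
    def blank_windows(self) -> np.ndarray:
        """[n_lines + 1, 2] array of margin-trimmed blank windows, one per
        gap (gap k precedes line k; gap n_lines trails the last line)."""
        half = self.gap / 2
        lo = self.separation_points - half + self.margin
        hi = self.separation_points + half - self.margin
        return np.column_stack([lo, hi])

    def line_index_of(self, times: np.ndarray) -> np.ndarray:
        """Map each timestamp to its line index, or -1 for blank readings."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, -1, dtype=int)
        for k, (lo, hi) in enumerate(self.line_windows):
            out[(times >= lo) & (times < hi)] = k
        return out

    def to_table(self) -> np.ndarray:
        """Audit export: rows of (line index, start s, end s)."""
        w = self.line_windows
        return np.column_stack([np.arange(self.n_lines), w[:, 0], w[:, 1]])


def segment_lines(
    series: TRASeries, timing: ScanTiming, *, allow_truncation: bool = False
) -> LineSegmentation:
    """Place separation points from the declared timing.

    Separation point k sits at
    ``first_line_start + k*line_interval - gap/2`` — the middle of the blank
    gap preceding line k.  If the record is too short for ``n_lines`` whole
    lines a :class:`CoverageError` reports how many fit; with
    ``allow_truncation=True`` the segmentation is truncated with a warning
    instead.
    """
    gap = timing.gap
    t_end = float(series.times[-1])
    # A line is usable when the record reaches at least the midpoint of the
    # blank following it (its separation bound).
    n_fit = int(np.floor((t_end - timing.first_line_start + gap / 2) / timing.line_interval))
    n_fit = max(0, min(n_fit, timing.n_lines))
    # ... but never count a line whose signal window is not fully recorded.
    while n_fit > 0 and timing.first_line_start + (n_fit - 1) * timing.line_interval + timing.line_duration > t_end:
        n_fit -= 1
    if n_fit < timing.n_lines:
        if not allow_truncation or n_fit == 0:
            raise CoverageError(
                f"record ends at t={t_end:g} s: only {n_fit} whole line(s) of the "
                f"declared {timing.n_lines} fit"
            )
        warnings.warn(
            f"record supports only {n_fit} of {timing.n_lines} declared lines; truncating",
            stacklevel=2,
        )
    n = n_fit if allow_truncation else timing.n_lines
    k = np.arange(n + 1)
    seps = timing.first_line_start + k * timing.line_interval - gap / 2
    return LineSegmentation(
        separation_points=seps,
        line_duration=timing.line_duration,
        gap=gap,
        margin=timing.resolved_margin,
    )


def adjust_separation(
    seg: LineSegmentation, point_index: int, delta: float
) -> LineSegmentation:
    """Move one separation point by ``delta`` seconds.

    The shifted point must remain strictly between its neighbours; the line
    and blank windows, being derived from the points, follow automatically.
    """
    pts = seg.separation_points.copy()
    if not 0 <= point_index < pts.size:
        raise AdjustmentError(f"separation point index {point_index} out of range")
    pts[point_index] += delta
    lo = pts[point_index - 1] if point_index > 0 else -np.inf
    hi = pts[point_index + 1] if point_index < pts.size - 1 else np.inf
    if not lo < pts[point_index] < hi:
        raise AdjustmentError(
            f"moving point {point_index} by {delta:g} s violates strict ordering"
        )
    return replace(seg, separation_points=pts)


@dataclass(frozen=True)
class BackgroundModel:
    """Per-(isotope, line) gas-blank background levels in CPS.

    ``levels`` is ``[n_lines, n_isotopes]``; ``windows_used[k]`` lists the
    blank-gap ids that contributed to line k's level.
    """

    levels: np.ndarray
    isotope_labels: list[str]
    method: str
    windows_used: list[tuple[int, ...]]

    @property
    def n_lines(self) -> int:
        return self.levels.shape[0]


def estimate_background(
    series: TRASeries,
    seg: LineSegmentation,
    method: str = "mean",
    *,
    scope: str = "per_line",
) -> BackgroundModel:
    """Estimate the background from the gas-blank windows.

    For each line the blank windows immediately before and after it (both,
    when they contain readings after the margins) are pooled and reduced by
    ``method`` (``mean`` or ``median``).  ``scope='global'`` pools every
    blank window into a single level applied to all lines.
    """
    if method not in ("mean", "median"):
        raise SchemaError("method must be 'mean' or 'median'")
    reducer = np.mean if method == "mean" else np.median
    blanks = seg.blank_windows
    in_blank = [
        np.nonzero((series.times >= lo) & (series.times <= hi))[0] for lo, hi in blanks
    ]
    n_lines, n_iso = seg.n_lines, series.n_isotopes
    levels = np.empty((n_lines, n_iso), dtype=float)
    used: list[tuple[int, ...]] = []
    if scope == "global":
        idx = np.concatenate([ix for ix in in_blank if ix.size]) if any(
            ix.size for ix in in_blank
        ) else np.empty(0, dtype=int)
        if idx.size == 0:
            raise BackgroundError("no blank readings available after margins")
        level = reducer(series.intensities[idx], axis=0)
        levels[:] = level
        used = [tuple(g for g, ix in enumerate(in_blank) if ix.size)] * n_lines
    elif scope == "per_line":
        for k in range(n_lines):
            ids = tuple(g for g in (k, k + 1) if in_blank[g].size)
            if not ids:
                raise BackgroundError(
                    f"line {k}: adjacent blank windows contain no readings after margins"
                )
            idx = np.concatenate([in_blank[g] for g in ids])
            levels[k] = reducer(series.intensities[idx], axis=0)
            used.append(ids)
    else:
        raise SchemaError("scope must be 'per_line' or 'global'")
    return BackgroundModel(
        levels=levels,
        isotope_labels=list(series.isotope_labels),
        method=method,
        windows_used=used,
    )


def subtract_background(
    series: TRASeries, seg: LineSegmentation, bg: BackgroundModel
) -> TRASeries:
    """Subtract per-line background levels from the line-window readings.

    Blank-window readings are returned untouched (they can be identified via
    ``seg.line_index_of``).  Post-subtraction intensities may be negative —
    clipping is deferred to rendering/quantification so ROI statistics stay
    unbiased.
    """
    if bg.n_lines < seg.n_lines:
        raise SchemaError("background model does not cover all lines")
    if bg.isotope_labels != series.isotope_labels:
        raise SchemaError("background model isotope labels do not match series")
    out = series.intensities.copy()
    line_idx = seg.line_index_of(series.times)
    for k in range(seg.n_lines):
        sel = line_idx == k
        out[sel] -= bg.levels[k]
    return TRASeries(
        times=series.times.copy(),
        intensities=out,
        isotope_labels=list(series.isotope_labels),
        source_files=series.source_files.copy(),
    )
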