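"""False-color rendering, RGB mixing, ratio images and raster export.

Intensity-to-color mapping: ``v = clip((I - lo) / (hi - lo), 0, 1)`` then
``v' = v**gamma``, then a named palette.  Contrast bounds default to an
auto-stretch (floor 0 after negative clipping, ceiling at the 99th
percentile of the valid cells) which is robust to signal spikes; explicit
``lo``/``hi`` always override.  Masked cells render fully transparent.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps

from .exceptions import GeometryError, SchemaError
from .gridding import IntensityGrid

SUPPORTED_FORMATS = ("PNG", "JPEG", "BMP")


@dataclass(frozen=True)
class DisplaySettings:
    """Contrast/γ settings for rendering one grid (or one RGB channel)."""

    lo: float | None = None
    hi: float | None = None
    gamma: float = 1.0
    colormap: str = "viridis"
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise SchemaError("gamma must be > 0")
        if self.lo is not None and self.hi is not None and not self.hi > self.lo:
            raise SchemaError("display ceiling must exceed floor")


def _resolve_bounds(grid: IntensityGrid, settings: DisplaySettings) -> tuple[float, float]:
    vals = grid.unmasked()
    if settings.clip_negative:
        vals = np.clip(vals, 0.0, None)
    lo = 0.0 if settings.lo is None else settings.lo
    if settings.hi is not None:
        hi = settings.hi
    else:
        hi = float(np.percentile(vals, 99)) if vals.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
    if hi <= lo:
        raise SchemaError("display ceiling must exceed floor")
    return lo, hi


def normalized_values(grid: IntensityGrid, settings: DisplaySettings) -> np.ndarray:
    """Per-cell normalized display value v' in [0, 1]; NaN on masked cells."""
    lo, hi = _resolve_bounds(grid, settings)
    vals = grid.values
    if settings.clip_negative:
        vals = np.where(grid.mask, np.clip(vals, 0.0, None), vals)
    v = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    v = v**settings.gamma
    return np.where(grid.mask, v, np.nan)


def _to_gray8(v: np.ndarray) -> np.ndarray:
    return np.rint(255.0 * np.nan_to_num(v)).astype(np.uint8)


def render_false_color(grid: IntensityGrid, settings: DisplaySettings | None = None) -> np.ndarray:
    """Render a grid as an 8-bit RGBA array (masked cells transparent).

    A grayscale palette (``gray``) maps v' directly to ``round(255 * v')``;
    other palettes are looked up in matplotlib's named colormaps.
    """
    settings = settings or DisplaySettings()
    v = normalized_values(grid, settings)
    alpha = np.where(grid.mask, 255, 0).astype(np.uint8)
    if settings.colormap == "gray":
        g = _to_gray8(v)
        rgba = np.stack([g, g, g, alpha], axis=-1)
    else:
        cmap = colormaps[settings.colormap]
        rgba = (cmap(np.nan_to_num(v)) * 255.0 + 0.5).astype(np.uint8)
        rgba[..., 3] = alpha
    return rgba


def rgb_mix(
    grid_r: IntensityGrid,
    grid_g: IntensityGrid,
    grid_b: IntensityGrid,
    settings_r: DisplaySettings | None = None,
    settings_g: DisplaySettings | None = None,
    settings_b: DisplaySettings | None = None,
) -> np.ndarray:
    """Combine three isotope grids into one RGB image.

    Each channel is normalized independently (grayscale mapping) so that,
    e.g., two co-located full-scale channels mix additively — red plus blue
    shows magenta.  A cell masked in any channel is transparent in the
    output.
    """
    if not (grid_r.same_geometry(grid_g) and grid_r.same_geometry(grid_b)):
        raise GeometryError("RGB channels must share shape and pitches")
    chans = []
    for grid, settings in ((grid_r, settings_r), (grid_g, settings_g), (grid_b, settings_b)):
        s = settings or DisplaySettings(colormap="gray")
        chans.append(_to_gray8(normalized_values(grid, s)))
    mask = grid_r.mask & grid_g.mask & grid_b.mask
    alpha = np.where(mask, 255, 0).astype(np.uint8)
    return np.stack([*chans, alpha], axis=-1)


def ratio_grid(
    numerator: IntensityGrid, denominator: IntensityGrid, min_denominator: float = 0.0
) -> IntensityGrid:
    """Cell-wise isotope ratio, masked where the denominator is too small.

    Cells with ``denominator <= min_denominator`` (and cells masked in
    either input) are masked rather than producing infinities.
    """
    if not numerator.same_geometry(denominator):
        raise GeometryError("ratio operands must share geometry")
    ok = numerator.mask & denominator.mask & (denominator.values > min_denominator)
    values = np.full(numerator.shape, np.nan)
    values[ok] = numerator.values[ok] / denominator.values[ok]
    return IntensityGrid(
        values=values,
        mask=ok,
        pitch_x=numerator.pitch_x,
        pitch_y=numerator.pitch_y,
        isotope_label=f"{numerator.isotope_label}/{denominator.isotope_label}",
        unit="ratio",
        origin=numerator.origin,
        row_files=numerator.row_files,
    )


def export_image(raster: np.ndarray, path: str | Path, format: str | None = None) -> None:
    """Write an 8-bit raster to PNG, JPEG or BMP.

    PNG and BMP are lossless: re-reading reproduces the array bit-exactly.
    JPEG drops the alpha channel (composited over black) and is lossy.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "JPG":
        fmt = "JPEG"
    if fmt not in SUPPORTED_FORMATS:
        raise SchemaError(
            f"unsupported image format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    arr = np.asarray(raster)
    if arr.dtype != np.uint8:
        raise SchemaError("raster must be 8-bit (uint8)")
    if fmt in ("JPEG", "BMP") and arr.ndim == 3 and arr.shape[-1] == 4:
        alpha = arr[..., 3:4].astype(np.float64) / 255.0
        arr = np.rint(arr[..., :3].astype(np.float64) * alpha).astype(np.uint8)
    iio.imwrite(path, arr, extension="." + fmt.lower().replace("jpeg", "jpg"))
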