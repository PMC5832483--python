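"""Semi-quantitative concentration mapping.

The chain is external sensitivity calibration plus per-pixel normalization:

1.  A raster run on a glass standard of known composition (e.g. NIST
    SRM610) gives a per-isotope relative sensitivity factor (RSF)
    ``s_iE = mean blank-subtracted CPS / C_E^STD`` in CPS per μg/g.
2.  Dividing a sample pixel's intensity by ``s_iE`` yields the relative
    response ``r_E`` — the μg/g value the pixel would have if the ablated
    mass and per-element sensitivity matched the standard run exactly.
    Atomic weight and isotope abundance cancel in this ratio because the
    same isotope is measured on both runs.
3.  The unknown ablated-mass/sensitivity ratio is collapsed into a single
    per-pixel factor α.  Either an internal standard pins it
    (``α = C_known / r_internal``), or the 100%-normalization closure
    fixes it per pixel: Σ_E α·r_E = 1 in element mode, or
    Σ_E α·f_ox(E)·r_E = 100 wt% in oxide mode, where ``f_ox`` is the
    fixed-valence oxide gravimetric factor (iron always as FeO).  α varies
    pixel to pixel because the ablated mass does.

Because α is solved per pixel, both modes are exactly invariant to scaling
all isotope intensities at a pixel by a common factor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants
from .exceptions import QuantError, SchemaError
from .gridding import IntensityGrid
from .regions import ROIPolygon, polygon_mask
from .segmentation import LineSegmentation
from .tra import TRASeries


@dataclass(frozen=True)
class StandardTable:
    """Known element concentrations of the calibration standard (μg/g)."""

    concentrations: dict[str, float]
    name: str = "standard"

    def __post_init__(self) -> None:
        for el, c in self.concentrations.items():
            if c <= 0:
                raise SchemaError(f"standard concentration for {el} must be > 0")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "StandardTable":
        df = _read_two_column(path)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])), name or Path(path).stem)


def _read_two_column(path: str | Path) -> pd.DataFrame:
    """Two-column delimited (species, value) table with one header row."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected a two-column (species, value) table")
    df = df.iloc[:, :2]
    df.iloc[:, 0] = df.iloc[:, 0].astype(str).str.strip()
    df.iloc[:, 1] = pd.to_numeric(df.iloc[:, 1])
    return df


@dataclass(frozen=True)
class RSFTable:
    """Per-isotope sensitivity factors (CPS per μg/g) from the standard run."""

    sensitivities: dict[str, float]
    isotope_to_element: dict[str, str]
    standard_name: str = "standard"

    def __post_init__(self) -> None:
        elements = list(self.isotope_to_element.values())
        if len(set(elements)) != len(elements):
            raise QuantError(
                "exactly one quantification isotope per element: duplicates "
                f"found for {sorted({e for e in elements if elements.count(e) > 1})}"
            )
        for iso, s in self.sensitivities.items():
            if s <= 0:
                raise QuantError(f"RSF for {iso} must be > 0")


def compute_rsf(
    standard_series: TRASeries,
    seg: LineSegmentation,
    table: StandardTable,
    isotopes: list[str] | None = None,
) -> RSFTable:
    """Derive the RSF table from a (background-subtracted) standard run.

    ``s_iE`` is the mean blank-subtracted CPS over all line readings of the
    standard run divided by the standard's known element concentration.
    ``isotopes`` selects the designated quantification isotope per element;
    default is every series isotope whose element appears in the table.
    """
    line_idx = seg.line_index_of(standard_series.times)
    on_line = line_idx >= 0
    if not on_line.any():
        raise QuantError("standard run contains no line readings")
    sens: dict[str, float] = {}
    iso_map: dict[str, str] = {}
    wanted = isotopes if isotopes is not None else standard_series.isotope_labels
    for label in wanted:
        element = constants.element_of_isotope(label)
        if isotopes is None and element not in table.concentrations:
            continue
        if element not in table.concentrations:
            raise QuantError(
                f"element {element} (isotope {label}) missing from standard table "
                f"{table.name!r}"
            )
        mean_cps = float(np.mean(standard_series.column(label)[on_line]))
        if mean_cps <= 0:
            raise QuantError(
                f"standard signal for {label} has non-positive mean ({mean_cps:g} CPS)"
            )
        sens[label] = mean_cps / table.concentrations[element]
        iso_map[label] = element
    if not sens:
        raise QuantError("no usable quantification isotopes found")
    return RSFTable(sensitivities=sens, isotope_to_element=iso_map, standard_name=table.name)


def relative_response(
    grids: dict[str, IntensityGrid], rsf: RSFTable
) -> dict[str, IntensityGrid]:
    """Per-element response grids ``r_E = I_iE / s_iE`` (μg/g at α = 1).

    Negative blank-subtracted intensities are floored at zero (with a
    counted warning) so trace-level noise cannot corrupt the normalization
    denominator.
    """
    out: dict[str, IntensityGrid] = {}
    n_floored = 0
    for iso, element in rsf.isotope_to_element.items():
        if iso not in grids:
            raise QuantError(f"no grid for designated quantification isotope {iso}")
        g = grids[iso]
        vals = g.values / rsf.sensitivities[iso]
        neg = g.mask & (vals < 0)
        n_floored += int(neg.sum())
        vals = np.where(neg, 0.0, vals)
        out[element] = IntensityGrid(
            values=np.where(g.mask, vals, np.nan),
            mask=g.mask.copy(),
            pitch_x=g.pitch_x,
            pitch_y=g.pitch_y,
            isotope_label=iso,
            unit="ug/g@alpha=1",
            origin=g.origin,
            row_files=g.row_files,
        )
    if n_floored:
        warnings.warn(
            f"{n_floored} negative response cell(s) floored at 0 before normalization",
            stacklevel=2,
        )
    return out


@dataclass
class QuantResult:
    """Per-element concentration maps plus the per-pixel α factor.

    ``concentrations`` maps species name (oxide formula in oxide mode,
    element symbol otherwise) to a grid in wt% (oxide mode) or mass
    fraction; ``alpha`` holds the per-pixel normalization factor, the only
    home of the unresolved ablated-mass and sensitivity-ratio terms.
    """

    concentrations: dict[str, IntensityGrid]
    alpha: IntensityGrid
    mode: str
    element_of_species: dict[str, str] = field(default_factory=dict)


def _common_geometry(responses: dict[str, IntensityGrid]) -> IntensityGrid:
    grids = list(responses.values())
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise QuantError("response grids must share geometry")
    return first


def quantify_norm100(
    responses: dict[str, IntensityGrid],
    oxide_mode: bool = True,
) -> QuantResult:
    """100%-normalization closure: solve α per pixel so species sum to unity.

    In oxide mode every element is expressed as its fixed-valence oxide and
    the per-pixel oxide sum is forced to 100 wt%; in element mode the mass
    fractions sum to 1.  Requires that every species actually present is
    measured — unmeasured species inflate the others.  Pixels with no
    positive response are masked.
    """
    if len(responses) < 2:
        raise QuantError("100%-normalization needs at least 2 elements")
    first = _common_geometry(responses)
    elements = sorted(responses)
    factors = {}
    for el in elements:
        f = constants.oxide_factor(el) if oxide_mode else 1.0
        if oxide_mode and el not in constants.OXIDE_STOICHIOMETRY:
            warnings.warn(
                f"no oxide stoichiometry for {el}; using gravimetric factor 1",
                stacklevel=2,
            )
        factors[el] = f

    shape = first.shape
    mask = np.ones(shape, dtype=bool)
    for el in elements:
        mask &= responses[el].mask
    total = np.zeros(shape)
    for el in elements:
        total += np.where(mask, factors[el] * responses[el].values, 0.0)
    ok = mask & (total > 0)
    if not ok.any():
        raise QuantError("no pixel has a positive summed response")
    alpha_vals = np.full(shape, np.nan)
    alpha_vals[ok] = 1.0 / total[ok]

    scale = 100.0 if oxide_mode else 1.0
    conc: dict[str, IntensityGrid] = {}
    species_map: dict[str, str] = {}
    for el in elements:
        name = constants.oxide_name(el) if oxide_mode else el
        vals = np.full(shape, np.nan)
        vals[ok] = scale * alpha_vals[ok] * factors[el] * responses[el].values[ok]
        conc[name] = IntensityGrid(
            values=vals,
            mask=ok.copy(),
            pitch_x=first.pitch_x,
            pitch_y=first.pitch_y,
            isotope_label=name,
            unit="wt%" if oxide_mode else "fraction",
            origin=first.origin,
            row_files=first.row_files,
        )
        species_map[name] = el
    alpha = IntensityGrid(
        values=alpha_vals,
        mask=ok.copy(),
        pitch_x=first.pitch_x,
        pitch_y=first.pitch_y,
        isotope_label="alpha",
        unit="alpha",
        origin=first.origin,
        row_files=first.row_files,
    )
    return QuantResult(
        concentrations=conc,
        alpha=alpha,
        mode="norm100_oxide" if oxide_mode else "norm100",
        element_of_species=species_map,
    )


def quantify_internal(
    responses: dict[str, IntensityGrid],
    internal_element: str,
    known_conc: float | np.ndarray,
    *,
    as_fraction: bool = False,
) -> QuantResult:
    """Internal standardization: pin α with one independently known element.

    ``known_conc`` is the internal element's concentration in μg/g — a
    scalar applied everywhere, or a per-pixel array where it was mapped
    independently (e.g. EPMA Si).  α = C_known / r_internal per pixel;
    pixels with non-positive internal response are masked, since the method
    only applies where the anchor concentration is meaningful.  Output is
    μg/g per element (``as_fraction`` divides by 1e6).
    """
    if internal_element not in responses:
        raise QuantError(f"internal element {internal_element} not among responses")
    first = _common_geometry(responses)
    r_int = responses[internal_element]
    known = np.broadcast_to(np.asarray(known_conc, dtype=float), first.shape)
    ok = r_int.mask & (r_int.values > 0) & np.isfinite(known)
    for el in responses:
        ok &= responses[el].mask
    if not ok.any():
        raise QuantError("internal-standard response is nowhere positive")
    alpha_vals = np.full(first.shape, np.nan)
    alpha_vals[ok] = known[ok] / r_int.values[ok]
    scale = 1e-6 if as_fraction else 1.0
    conc: dict[str, IntensityGrid] = {}
    for el in sorted(responses):
        vals = np.full(first.shape, np.nan)
        vals[ok] = scale * alpha_vals[ok] * responses[el].values[ok]
        conc[el] = IntensityGrid(
            values=vals,
            mask=ok.copy(),
            pitch_x=first.pitch_x,
            pitch_y=first.pitch_y,
            isotope_label=el,
            unit="fraction" if as_fraction else "ug/g",
            origin=first.origin,
            row_files=first.row_files,
        )
    alpha = IntensityGrid(
        values=alpha_vals,
        mask=ok.copy(),
        pitch_x=first.pitch_x,
        pitch_y=first.pitch_y,
        isotope_label="alpha",
        unit="alpha",
        origin=first.origin,
        row_files=first.row_files,
    )
    return QuantResult(
        concentrations=conc,
        alpha=alpha,
        mode="internal_standard",
        element_of_species={el: el for el in responses},
    )


def roi_stats(
    quant: QuantResult, region: ROIPolygon | tuple[float, float, float, float]
) -> pd.DataFrame:
    """Unweighted mean, 1σ standard deviation (n−1 denominator) and n per
    species over the region's member pixels.  ``region`` may be a polygon
    or an ``(x0, y0, x1, y1)`` rectangle; single-pixel regions report the
    value with SD = NaN."""
    if not isinstance(region, ROIPolygon):
        region = ROIPolygon.rectangle("rect", *region)
    rows = []
    for species, grid in quant.concentrations.items():
        member = polygon_mask(grid, region)
        n = int(member.sum())
        if n == 0:
            raise QuantError(f"region {region.label!r} contains no valid pixels")
        vals = grid.values[member]
        rows.append(
            {
                "species": species,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if n > 1 else float("nan"),
                "n": n,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def deviation_table(
    measured: dict[str, float] | pd.Series,
    reference: dict[str, float] | pd.Series,
) -> pd.DataFrame:
    """Relative deviation of measured vs reference values per species.

    The deviation column is ``measured / reference − 1``, rounded to 3
    decimals for reporting (full precision kept in ``deviation_raw``).
    Species with a zero reference are skipped with a warning; species
    missing from either table are omitted.
    """
    measured = dict(measured)
    reference = dict(reference)
    rows = []
    for species in measured:
        if species not in reference:
            continue
        ref = reference[species]
        if ref == 0:
            warnings.warn(f"reference value for {species} is zero; skipped", stacklevel=2)
            continue
        dev = measured[species] / ref - 1.0
        rows.append(
            {
                "species": species,
                "measured": measured[species],
                "reference": ref,
                "deviation": round(dev, 3),
                "deviation_raw": dev,
            }
        )
    return pd.DataFrame(rows).set_index("species")
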