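"""Forward simulation of a raster LA-ICPMS acquisition from a known phantom.

The simulator emits the same alternating line-scan / gas-blank structure an
instrument produces: readings every ``reading_interval`` seconds (the
multi-isotope cycle, dwell × number of isotopes), pure signal
``ε_E · C_E(x, y) · m(x, y)`` plus a constant gas-blank background during
ablation, background only during blanks.  Optional exponential washout
tailing (single time constant, the dominant aerosol-transport effect) and
Poisson counting noise complete the instrument model.  Every stage of the
reconstruction pipeline can be checked against the returned truth bundle;
with zero washout and no noise the pipeline is the identity on the phantom
at the sampled pixel centers.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import shapely

from . import constants
from .exceptions import SchemaError
from .gridding import IntensityGrid, RasterGeometry
from .segmentation import LineSegmentation, ScanTiming
from .tra import TRADialect, TRASeries, write_tra


@dataclass(frozen=True)
class Phase:
    """One homogeneous region of the phantom.

    ``composition`` maps element symbol to concentration; ``unit`` is
    ``ug/g`` or ``oxide_wt%`` (fixed-valence oxide weight percent, converted
    internally to element μg/g via the gravimetric factors).
    """

    vertices: tuple[tuple[float, float], ...]
    composition: dict[str, float]
    unit: str = "ug/g"
    label: str = ""

    def __post_init__(self) -> None:
        if self.unit not in ("ug/g", "oxide_wt%"):
            raise SchemaError("phase unit must be 'ug/g' or 'oxide_wt%'")
        if any(v < 0 for v in self.composition.values()):
            raise SchemaError("phase concentrations must be non-negative")
        if len(self.vertices) < 3:
            raise SchemaError("phase polygon needs at least 3 vertices")

    def element_ugg(self) -> dict[str, float]:
        """Composition as element μg/g."""
        if self.unit == "ug/g":
            return dict(self.composition)
        out = {}
        for el, wt in self.composition.items():
            out[el] = wt * 1e4 / constants.oxide_factor(el)
        return out


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth sample model.

    ``sensitivities`` are per-element ε in CPS per μg/g of ablated signal;
    ``background_cps`` is the gas-blank level (scalar, or per isotope);
    ``washout_tau`` the aerosol washout time constant in seconds (≈ 2 s for
    a conventional cell; 0 disables tailing); ``mass_modulation`` an
    optional ``f(x, y) -> factor`` emulating spatially varying ablated mass
    (this is exactly what the per-pixel α absorbs downstream).
    """

    width: float
    height: float
    phases: tuple[Phase, ...]
    sensitivities: dict[str, float]
    background_cps: float | dict[str, float] = 0.0
    washout_tau: float = 0.0
    noise: str = "none"
    seed: int = 0
    mass_modulation: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.washout_tau < 0:
            raise SchemaError("washout_tau must be >= 0")
        if self.noise not in ("none", "poisson"):
            raise SchemaError("noise must be 'none' or 'poisson'")
        if not self.phases:
            raise SchemaError("phantom needs at least one phase")

    def background_for(self, isotope: str) -> float:
        if isinstance(self.background_cps, dict):
            return float(self.background_cps.get(isotope, 0.0))
        return float(self.background_cps)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Raster timing/geometry of the simulated run.

    Defaults mirror a typical silicate imaging run: 10 μm/s raster rate,
    11 μm line spacing, 60 lines, 30 s start-to-start line interval,
    0.35 s multi-isotope reading cycle.
    """

    isotopes: tuple[str, ...]
    raster_rate: float = 10.0
    line_spacing: float = 11.0
    line_length: float = 200.0
    n_lines: int = 60
    reading_interval: float = 0.35
    line_interval: float = 30.0
    first_line_start: float = 5.0

    def __post_init__(self) -> None:
        if not self.isotopes:
            raise SchemaError("acquisition must monitor at least one isotope")
        if self.raster_rate <= 0 or self.line_spacing <= 0 or self.line_length <= 0:
            raise SchemaError("raster_rate, line_spacing, line_length must be > 0")
        if self.reading_interval <= 0:
            raise SchemaError("reading_interval must be > 0")
        if self.line_interval <= self.line_duration:
            raise SchemaError("line_interval must exceed the line duration")

    @property
    def line_duration(self) -> float:
        return self.line_length / self.raster_rate

    def timing(self, blank_margin: float | None = None) -> ScanTiming:
        return ScanTiming(
            first_line_start=self.first_line_start,
            line_duration=self.line_duration,
            line_interval=self.line_interval,
            n_lines=self.n_lines,
            blank_margin=blank_margin,
        )

    def geometry(self) -> RasterGeometry:
        return RasterGeometry(
            raster_rate=self.raster_rate, line_spacing=self.line_spacing
        )

    @property
    def dwell(self) -> float:
        """Per-isotope integration time within one reading cycle."""
        return self.reading_interval / len(self.isotopes)


@dataclass
class TruthBundle:
    """Ground truth aligned with the grid the pipeline will reconstruct."""

    intensity: dict[str, IntensityGrid]  # pure (background-free) signal, CPS
    conc_ugg: dict[str, IntensityGrid]  # element concentration, μg/g
    oxide_wt: dict[str, IntensityGrid]  # fixed-valence oxide, wt%
    mass: IntensityGrid  # ablated-mass modulation factor
    segmentation: LineSegmentation
    line_index: np.ndarray  # per reading; -1 = gas blank
    is_ablation: np.ndarray


@dataclass
class SimulatedRun:
    series: TRASeries
    truth: TruthBundle
    phantom: PhantomSpec
    acquisition: AcquisitionSpec


def _element_maps(
    phantom: PhantomSpec, x: np.ndarray, y: np.ndarray
) -> dict[str, np.ndarray]:
    """Element concentration (μg/g) at sample points; first phase containing
    a point wins, points outside every phase get zero."""
    elements: set[str] = set()
    for ph in phantom.phases:
        elements.update(ph.composition)
    out = {el: np.zeros(x.shape) for el in sorted(elements)}
    unassigned = np.ones(x.shape, dtype=bool)
    for ph in phantom.phases:
        poly = shapely.Polygon(ph.vertices)
        inside = shapely.intersects_xy(poly, x.ravel(), y.ravel()).reshape(x.shape)
        take = inside & unassigned
        comp = ph.element_ugg()
        for el in out:
            out[el][take] = comp.get(el, 0.0)
        unassigned &= ~take
    return out


def ideal_signal(phantom: PhantomSpec, acq: AcquisitionSpec) -> SimulatedRun:
    """Noise-free, washout-free forward model.

    Reading times are ``i * reading_interval``; during line k (half-open
    window) the laser sits at ``x = (t - line_start_k) * raster_rate``,
    ``y = k * line_spacing``.  Returns the raw series (signal + background)
    and the truth bundle sampled at exactly the pixel centers the gridder
    reconstructs.
    """
    dt = acq.reading_interval
    total = acq.first_line_start + acq.n_lines * acq.line_interval
    n_read = int(np.floor(total / dt)) + 1
    times = np.arange(n_read) * dt

    line_index = np.full(n_read, -1, dtype=int)
    x_pos = np.zeros(n_read)
    y_pos = np.zeros(n_read)
    for k in range(acq.n_lines):
        start = acq.first_line_start + k * acq.line_interval
        sel = (times >= start) & (times < start + acq.line_duration)
        line_index[sel] = k
        x_pos[sel] = (times[sel] - start) * acq.raster_rate
        y_pos[sel] = k * acq.line_spacing
    is_abl = line_index >= 0

    conc = _element_maps(phantom, x_pos, y_pos)
    if phantom.mass_modulation is not None:
        mass = np.asarray(phantom.mass_modulation(x_pos, y_pos), dtype=float)
        mass = np.broadcast_to(mass, x_pos.shape).copy()
    else:
        mass = np.ones(n_read)

    intens = np.zeros((n_read, len(acq.isotopes)))
    pure = np.zeros_like(intens)
    for j, iso in enumerate(acq.isotopes):
        el = constants.element_of_isotope(iso)
        eps = phantom.sensitivities.get(el, 0.0)
        sig = np.where(is_abl, eps * conc.get(el, np.zeros(n_read)) * mass, 0.0)
        pure[:, j] = sig
        intens[:, j] = sig + phantom.background_for(iso)

    series = TRASeries(
        times=times, intensities=intens, isotope_labels=list(acq.isotopes)
    )
    truth = _build_truth(phantom, acq, line_index, pure, conc, mass)
    return SimulatedRun(series=series, truth=truth, phantom=phantom, acquisition=acq)


def _build_truth(
    phantom: PhantomSpec,
    acq: AcquisitionSpec,
    line_index: np.ndarray,
    pure: np.ndarray,
    conc: dict[str, np.ndarray],
    mass: np.ndarray,
) -> TruthBundle:
    n_lines = acq.n_lines
    rows = [np.nonzero(line_index == k)[0] for k in range(n_lines)]
    n_cols = max(sel.size for sel in rows)
    pitch_x = acq.raster_rate * acq.reading_interval
    common = dict(pitch_x=pitch_x, pitch_y=acq.line_spacing, origin=(0.0, 0.0))

    def pack(per_reading: np.ndarray, label: str, unit: str) -> IntensityGrid:
        vals = np.full((n_lines, n_cols), np.nan)
        msk = np.zeros((n_lines, n_cols), dtype=bool)
        for k, sel in enumerate(rows):
            vals[k, : sel.size] = per_reading[sel]
            msk[k, : sel.size] = True
        return IntensityGrid(values=vals, mask=msk, isotope_label=label, unit=unit, **common)

    intensity = {
        iso: pack(pure[:, j], iso, "CPS") for j, iso in enumerate(acq.isotopes)
    }
    conc_grids = {el: pack(conc[el], el, "ug/g") for el in conc}
    oxide = {}
    for el in conc:
        f = constants.oxide_factor(el)
        oxide[constants.oxide_name(el)] = pack(
            conc[el] * f * 1e-4, constants.oxide_name(el), "wt%"
        )
    seg = LineSegmentation(
        separation_points=acq.first_line_start
        + np.arange(n_lines + 1) * acq.line_interval
        - (acq.line_interval - acq.line_duration) / 2,
        line_duration=acq.line_duration,
        gap=acq.line_interval - acq.line_duration,
        margin=acq.timing().resolved_margin,
    )
    return TruthBundle(
        intensity=intensity,
        conc_ugg=conc_grids,
        oxide_wt=oxide,
        mass=pack(mass, "mass", "factor"),
        segmentation=seg,
        line_index=line_index,
        is_ablation=line_index >= 0,
    )


def apply_washout(series: TRASeries, tau: float) -> TRASeries:
    """Convolve every channel with a causal exponential washout kernel.

    Kernel ``k_j = (1 - λ) λ^j`` with ``λ = exp(-Δt / tau)``, renormalized
    to unit sum after truncation, so integrated counts are conserved.
    ``tau = 0`` is the identity.
    """
    if tau < 0:
        raise SchemaError("tau must be >= 0")
    if tau == 0:
        return TRASeries(
            times=series.times.copy(),
            intensities=series.intensities.copy(),
            isotope_labels=list(series.isotope_labels),
            source_files=series.source_files.copy(),
        )
    dt = series.reading_interval
    lam = np.exp(-dt / tau)
    n_k = max(1, int(np.ceil(np.log(1e-12) / np.log(lam))) + 1)
    kernel = (1 - lam) * lam ** np.arange(n_k)
    kernel /= kernel.sum()
    out = np.empty_like(series.intensities)
    for j in range(series.n_isotopes):
        out[:, j] = np.convolve(series.intensities[:, j], kernel)[: series.n_readings]
    return TRASeries(
        times=series.times.copy(),
        intensities=out,
        isotope_labels=list(series.isotope_labels),
        source_files=series.source_files.copy(),
    )


def add_noise(series: TRASeries, dwell: float, seed: int) -> TRASeries:
    """Poisson counting noise: counts per reading drawn with mean
    ``CPS * dwell``, converted back to CPS.  Bit-reproducible per seed."""
    if dwell <= 0:
        raise SchemaError("dwell must be > 0")
    rng = np.random.default_rng(seed)
    mean_counts = np.clip(series.intensities, 0.0, None) * dwell
    counts = rng.poisson(mean_counts)
    return TRASeries(
        times=series.times.copy(),
        intensities=counts / dwell,
        isotope_labels=list(series.isotope_labels),
        source_files=series.source_files.copy(),
    )


def simulate_run(phantom: PhantomSpec, acq: AcquisitionSpec) -> SimulatedRun:
    """Full forward model: ideal signal, then washout, then noise, as the
    phantom spec dictates."""
    run = ideal_signal(phantom, acq)
    series = run.series
    if phantom.washout_tau > 0:
        series = apply_washout(series, phantom.washout_tau)
    if phantom.noise == "poisson":
        series = add_noise(series, acq.dwell, phantom.seed)
    return SimulatedRun(series=series, truth=run.truth, phantom=phantom, acquisition=acq)


def uniform_standard_run(
    table_concentrations: dict[str, float],
    acq: AcquisitionSpec,
    sensitivities: dict[str, float],
    background_cps: float | dict[str, float] = 0.0,
    *,
    noise: str = "none",
    seed: int = 1,
    sensitivity_ratio: dict[str, float] | None = None,
) -> SimulatedRun:
    """Simulate the external-standard raster (homogeneous glass).

    ``sensitivity_ratio`` optionally perturbs per-element ε on the standard
    relative to the sample run, to study the bias introduced by assuming
    the ratio is element-constant.
    """
    eps = dict(sensitivities)
    if sensitivity_ratio:
        for el, ratio in sensitivity_ratio.items():
            eps[el] = eps.get(el, 0.0) * ratio
    margin = 2 * max(acq.line_length, (acq.n_lines) * acq.line_spacing)
    phase = Phase(
        vertices=(
            (-margin, -margin),
            (margin, -margin),
            (margin, margin),
            (-margin, margin),
        ),
        composition=dict(table_concentrations),
        unit="ug/g",
        label="standard",
    )
    phantom = PhantomSpec(
        width=acq.line_length,
        height=acq.n_lines * acq.line_spacing,
        phases=(phase,),
        sensitivities=eps,
        background_cps=background_cps,
        noise=noise,
        seed=seed,
    )
    return simulate_run(phantom, acq)


def random_phantom(
    rng: np.random.Generator,
    acq: AcquisitionSpec,
    n_phases: int = 3,
    elements: Sequence[str] = ("Si", "Mg", "Fe", "Al", "Ca", "Na"),
    eps_range: tuple[float, float] = (30.0, 60.0),
    background_cps: float = 50.0,
    washout_tau: float = 0.0,
    noise: str = "none",
    seed: int = 0,
) -> PhantomSpec:
    """Draw a random multi-phase silicate-like phantom covering the scan area.

    Phases are vertical strips with random boundaries; each phase's
    composition is a random oxide mixture summing to exactly 100 wt%, so
    the 100%-normalization closure holds by construction.  Sensitivities ε
    are drawn per element from ``eps_range`` (CPS per μg/g); the default
    range keeps every major species above ~10⁴ counts per reading at
    typical dwell times, where Poisson noise is at the percent level.
    """
    width = acq.line_length
    height = acq.n_lines * acq.line_spacing
    cuts = np.sort(rng.uniform(0.15, 0.85, size=n_phases - 1)) * width
    edges = np.concatenate([[-1.0], cuts, [width + 1.0]])
    phases = []
    for i in range(n_phases):
        x0, x1 = edges[i], edges[i + 1]
        wt = rng.dirichlet(np.full(len(elements), 2.0)) * 100.0
        phases.append(
            Phase(
                vertices=(
                    (x0, -acq.line_spacing),
                    (x1, -acq.line_spacing),
                    (x1, height + acq.line_spacing),
                    (x0, height + acq.line_spacing),
                ),
                composition={el: float(w) for el, w in zip(elements, wt)},
                unit="oxide_wt%",
                label=f"phase{i}",
            )
        )
    sens = {el: float(rng.uniform(*eps_range)) for el in elements}
    return PhantomSpec(
        width=width,
        height=height,
        phases=tuple(phases),
        sensitivities=sens,
        background_cps=background_cps,
        washout_tau=washout_tau,
        noise=noise,
        seed=seed,
    )


def emit_run(
    run: SimulatedRun,
    dialect: TRADialect,
    out_dir: str | Path,
    n_split: int = 1,
    prefix: str = "tra",
) -> list[Path]:
    """Write the run's series as ``n_split`` contiguous TRA files.

    Reproduces the common field situation where one long acquisition is
    saved as several sequential files; stitching the files back must
    reproduce the in-memory series element-wise.
    """
    if n_split < 1:
        raise SchemaError("n_split must be >= 1")
    series = run.series
    if n_split > series.n_readings // 2:
        raise SchemaError("n_split too large: each file needs at least 2 readings")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bounds = np.linspace(0, series.n_readings, n_split + 1).astype(int)
    paths: list[Path] = []
    for i in range(n_split):
        lo, hi = bounds[i], bounds[i + 1]
        part = TRASeries(
            times=series.times[lo:hi],
            intensities=series.intensities[lo:hi],
            isotope_labels=list(series.isotope_labels),
        )
        path = out_dir / f"{prefix}_{i:02d}.csv"
        write_tra(part, path, dialect)
        paths.append(path)
    return paths
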