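"""Shared scenario fixtures: a small two-phase silicate-like raster run."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from elemap.gridding import build_grids
from elemap.segmentation import estimate_background, segment_lines, subtract_background
from elemap.simulate import AcquisitionSpec, PhantomSpec, Phase, simulate_run

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

ISOTOPES = ("28Si", "24Mg", "56Fe")
SENSITIVITIES = {"Si": 2.0, "Mg": 3.0, "Fe": 1.5}

# Two mineral-like phases split at x = 50 μm, oxide compositions summing to
# 100 wt% so the normalization closure is exact.
PHASE_A = {"Si": 58.0, "Mg": 32.0, "Fe": 10.0}
PHASE_B = {"Si": 40.0, "Mg": 50.0, "Fe": 10.0}


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionSpec:
    """A desk-scale raster: 6 lines of 100 μm at 10 μm/s (10 s ablation,
    5 s gas blank), 0.35 s reading cycle."""
    return AcquisitionSpec(
        isotopes=ISOTOPES,
        raster_rate=10.0,
        line_spacing=11.0,
        line_length=100.0,
        n_lines=6,
        reading_interval=0.35,
        line_interval=15.0,
        first_line_start=5.0,
    )


def two_phase_phantom(
    background: float = 50.0, washout_tau: float = 0.0, noise: str = "none", seed: int = 0
) -> PhantomSpec:
    big = 1e4
    return PhantomSpec(
        width=100.0,
        height=66.0,
        phases=(
            Phase(((-big, -big), (50.0, -big), (50.0, big), (-big, big)),
                  PHASE_A, unit="oxide_wt%", label="A"),
            Phase(((50.0, -big), (big, -big), (big, big), (50.0, big)),
                  PHASE_B, unit="oxide_wt%", label="B"),
        ),
        sensitivities=SENSITIVITIES,
        background_cps=background,
        washout_tau=washout_tau,
        noise=noise,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_run(small_acq):
    """Noise-free, washout-free two-phase run with 50 CPS background."""
    return simulate_run(two_phase_phantom(), small_acq)


@pytest.fixture(scope="session")
def clean_grids(clean_run, small_acq):
    """Background-subtracted intensity grids reconstructed from clean_run."""
    seg = segment_lines(clean_run.series, small_acq.timing())
    bg = estimate_background(clean_run.series, seg)
    sub = subtract_background(clean_run.series, seg, bg)
    return build_grids(sub, seg, small_acq.geometry())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
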