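"""Bundled reference data.

One small table ships with the package: a published EPMA vs LA-ICPMS
(100%-normalization, oxide mode) major-element comparison for a
garnet/wadsleyite silicate sample.  It exercises the deviation-report
arithmetic and anchors the expected accuracy of the semi-quantification
(major-oxide discrepancies generally below 15%).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

_FILENAME = "silicate_epma_comparison.csv"


def silicate_epma_comparison() -> pd.DataFrame:
    """EPMA vs LA-ICPMS oxide means per phase.

    Columns: phase, species, n (ROI pixel count), epma_wt, icpms_mean_wt,
    icpms_sd_wt (1σ), deviation_printed ((ICPMS/EPMA)−1 as published).
    """
    ref = resources.files("elemap.data").joinpath(_FILENAME)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def phase_means(df: pd.DataFrame, phase: str) -> dict[str, float]:
    """LA-ICPMS mean wt% per species for one phase (measured species only)."""
    sub = df[(df["phase"] == phase) & df["icpms_mean_wt"].notna()]
    return dict(zip(sub["species"], sub["icpms_mean_wt"]))


def phase_reference(df: pd.DataFrame, phase: str) -> dict[str, float]:
    """EPMA reference wt% per species for one phase."""
    sub = df[df["phase"] == phase]
    return dict(zip(sub["species"], sub["epma_wt"]))
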