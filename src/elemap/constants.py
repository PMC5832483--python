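"""Element constants used by the semi-quantification step.

Atomic weights and isotope abundances are standard IUPAC values.  They cancel
between the sample and standard runs when the same isotope is measured on both
sides, so quantification results depend on them only through the oxide
gravimetric factors; they are kept for documentation and for the factors.
"""
from __future__ import annotations

import re

# Conventional atomic weights (g/mol).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011,
    "N": 14.007, "O": 15.999, "F": 18.998, "Na": 22.990, "Mg": 24.305,
    "Al": 26.982, "Si": 28.085, "P": 30.974, "S": 32.06, "K": 39.098,
    "Ca": 40.078, "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996,
    "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546,
    "Zn": 65.38, "Ga": 69.723, "Ge": 72.630, "Rb": 85.468, "Sr": 87.62,
    "Y": 88.906, "Zr": 91.224, "Nb": 92.906, "Ba": 137.33, "La": 138.91,
    "Ce": 140.12, "Pr": 140.91, "Nd": 144.24, "Sm": 150.36, "Eu": 151.96,
    "Gd": 157.25, "Tb": 158.93, "Dy": 162.50, "Ho": 164.93, "Er": 167.26,
    "Tm": 168.93, "Yb": 173.05, "Lu": 174.97, "Hf": 178.49, "Ta": 180.95,
    "W": 183.84, "Pb": 207.2, "Th": 232.04, "U": 238.03,
}

# Natural isotope abundances (fraction) for isotopes commonly monitored in
# raster imaging runs.  Incomplete by design: abundances cancel out in the
# sample/standard intensity ratio and are never required for quantification.
ISOTOPE_ABUNDANCES: dict[str, float] = {
    "7Li": 0.9241, "23Na": 1.0000, "24Mg": 0.7899, "25Mg": 0.1000,
    "27Al": 1.0000, "28Si": 0.9223, "29Si": 0.0467, "31P": 1.0000,
    "39K": 0.9326, "43Ca": 0.00135, "44Ca": 0.02086, "45Sc": 1.0000,
    "47Ti": 0.0744, "49Ti": 0.0541, "51V": 0.9975, "52Cr": 0.8379,
    "53Cr": 0.0950, "55Mn": 1.0000, "56Fe": 0.9175, "57Fe": 0.0212,
    "59Co": 1.0000, "60Ni": 0.2622, "63Cu": 0.6915, "66Zn": 0.2773,
    "88Sr": 0.8258, "89Y": 1.0000, "90Zr": 0.5145, "137Ba": 0.1123,
    "139La": 0.9991, "140Ce": 0.8845, "146Nd": 0.1722, "147Sm": 0.1499,
    "153Eu": 0.5219, "157Gd": 0.1565, "159Tb": 1.0000, "163Dy": 0.2486,
    "166Er": 0.3350, "172Yb": 0.2183, "175Lu": 0.9740, "208Pb": 0.5240,
    "232Th": 0.9998, "238U": 0.9927,
}

# Oxide stoichiometry with a fixed valence per element (Fe is always FeO).
# element -> (oxide formula name, n_element, n_oxygen)
OXIDE_STOICHIOMETRY: dict[str, tuple[str, int, int]] = {
    "Si": ("SiO2", 1, 2),
    "Ti": ("TiO2", 1, 2),
    "Al": ("Al2O3", 2, 3),
    "Fe": ("FeO", 1, 1),
    "Mn": ("MnO", 1, 1),
    "Mg": ("MgO", 1, 1),
    "Ca": ("CaO", 1, 1),
    "Na": ("Na2O", 2, 1),
    "K": ("K2O", 2, 1),
    "Cr": ("Cr2O3", 2, 3),
    "Ni": ("NiO", 1, 1),
    "P": ("P2O5", 2, 5),
}

_ISOTOPE_RE = re.compile(r"^\s*(\d+)\s*([A-Z][a-z]?)\s*$")
_ISOTOPE_RE_REV = re.compile(r"^\s*([A-Z][a-z]?)\s*[-_ ]?\s*(\d+)\s*$")


def oxide_factor(element: str) -> float:
    """Gravimetric factor M(oxide) / (n_E * Ar(E)) converting element mass to
    oxide mass at the fixed valence.  Elements with no oxide entry get 1.0
    (reported as the element itself); callers decide whether to warn.
    """
    entry = OXIDE_STOICHIOMETRY.get(element)
    if entry is None:
        return 1.0
    _, n_e, n_o = entry
    ar = ATOMIC_WEIGHTS[element]
    return (n_e * ar + n_o * ATOMIC_WEIGHTS["O"]) / (n_e * ar)


def oxide_name(element: str) -> str:
    entry = OXIDE_STOICHIOMETRY.get(element)
    return entry[0] if entry is not None else element


def element_of_isotope(label: str) -> str:
    """Extract the element symbol from an isotope label like ``157Gd`` or
    ``Gd157``.  Raises ValueError for labels that are not isotope-like."""
    m = _ISOTOPE_RE.match(label) or _ISOTOPE_RE_REV.match(label)
    if m is None:
        raise ValueError(f"cannot parse isotope label {label!r}")
    groups = m.groups()
    symbol = groups[1] if groups[0].isdigit() else groups[0]
    if symbol not in ATOMIC_WEIGHTS:
        raise ValueError(f"unknown element symbol {symbol!r} in {label!r}")
    return symbol
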