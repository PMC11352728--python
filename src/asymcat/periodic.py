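"""Bundled element tables: covalent and van der Waals radii, atomic numbers.

Covalent radii are the Cordero single-bond set; van der Waals radii are
Bondi's, with the gaps (notably Rh and the early transition metals, which
Bondi never tabulated) filled with the 2.0 A value customary in buried-volume
work. Both tables ship as CSV data so they can be inspected and versioned.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9,
    "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16,
    "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Ti": 22, "Cr": 24, "Mn": 25,
    "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30, "Ga": 31, "Ge": 32,
    "As": 33, "Se": 34, "Br": 35, "Mo": 42, "Ru": 44, "Rh": 45, "Pd": 46,
    "Ag": 47, "Sn": 50, "Sb": 51, "Te": 52, "I": 53, "Ir": 77, "Pt": 78,
    "Au": 79,
}


def _load(name: str) -> dict[str, float]:
    with resources.files("asymcat.data").joinpath(name).open() as fh:
        table = pd.read_csv(fh)
    return dict(zip(table["element"], table["radius"].astype(float)))


COVALENT_RADII: dict[str, float] = _load("covalent_radii.csv")
VDW_RADII: dict[str, float] = _load("vdw_radii.csv")
ATOMIC_NUMBERS: dict[str, int] = dict(_ATOMIC_NUMBERS)


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise KeyError(f"no covalent radius for element {element!r}") from None


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element]
    except KeyError:
        raise KeyError(f"no van der Waals radius for element {element!r}") from None
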