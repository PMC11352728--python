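"""Experimental design, modeling-subset selection and target derivation.

The screening campaign covers five prochiral olefins (SM1-SM5) against a
192-ligand Rh precatalyst library over 37 96-well plates (3552 wells). For
modeling, one uniform condition per substrate is kept — methanol
throughout, 25 C / 5 bar / 1 h for SM1-SM3 and 50 C / 5 bar / 16 h for
SM4-SM5 — leaving 960 points. Enantioselectivity is modeled as the
transition-state free-energy difference ddG = R*T*ln((1+ee)/(1-ee)), which
is near-normally distributed where ee itself is not; reactivity is a
binary high/low conversion class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .io import HTERecord

__all__ = [
    "R_KJ_PER_MOL_K",
    "DesignRow",
    "canonical_design",
    "select_modeling_subset",
    "ee_to_ddg",
    "ddg_to_ee",
    "label_conversion",
]

logger = logging.getLogger(__name__)

#: gas constant in kJ mol^-1 K^-1
R_KJ_PER_MOL_K = 8.314462618e-3

WELLS_PER_PLATE = 96


@dataclass(frozen=True)
class DesignRow:
    """One condition row of the plate design table."""

    substrate_id: str
    solvent: str
    temperature_C: float
    pressure_bar: float
    time_h: float
    n_points: int
    selected: bool

    def __post_init__(self) -> None:
        if self.n_points % WELLS_PER_PLATE != 0:
            raise ValueError(
                f"n_points {self.n_points} is not a multiple of {WELLS_PER_PLATE}"
            )

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15


def canonical_design() -> list[DesignRow]:
    """The plate design shipped as package data (17 condition rows).

    Point counts sum to 3552 (37 plates); the five selected rows of 192
    points each make up the 960-point modeling subset.
    """
    with resources.files("asymcat.data").joinpath("design_table.csv").open() as fh:
        table = pd.read_csv(fh)
    return [
        DesignRow(
            substrate_id=row.substrate_id,
            solvent=row.solvent,
            temperature_C=float(row.temperature_C),
            pressure_bar=float(row.pressure_bar),
            time_h=float(row.time_h),
            n_points=int(row.n_points),
            selected=bool(row.selected),
        )
        for row in table.itertuples(index=False)
    ]


def _matches(record: HTERecord, row: DesignRow, tol: float = 1e-6) -> bool:
    return (
        record.substrate_id == row.substrate_id
        and record.solvent == row.solvent
        and abs(record.temperature - row.temperature_K) <= tol
        and abs(record.pressure - row.pressure_bar) <= tol
        and abs(record.time - row.time_h) <= tol
    )


def select_modeling_subset(
    records: Sequence[HTERecord], design: Sequence[DesignRow] | None = None
) -> list[HTERecord]:
    """Keep only records matching the selected design rows.

    Records matching no design row at all are dropped with a warning; the
    filter is idempotent.
    """
    if design is None:
        design = canonical_design()
    selected_rows = [r for r in design if r.selected]
    out: list[HTERecord] = []
    n_unmatched = 0
    for rec in records:
        if any(_matches(rec, row) for row in selected_rows):
            out.append(rec)
        elif not any(_matches(rec, row) for row in design):
            n_unmatched += 1
    if n_unmatched:
        logger.warning("%d records matched no design row and were dropped", n_unmatched)
    return out


def ee_to_ddg(ee: float, temperature: float) -> float:
    """ddG (kJ/mol) of the stereo-determining transition states from ee.

    Positive ddG favors the (+)-ee enantiomer; ``temperature`` in K.
    """
    if abs(ee) >= 1.0:
        raise ValueError(f"|ee| = {abs(ee)} >= 1 implies infinite ddG")
    return R_KJ_PER_MOL_K * temperature * math.log((1.0 + ee) / (1.0 - ee))


def ddg_to_ee(ddg: float, temperature: float) -> float:
    """Inverse of :func:`ee_to_ddg` (a tanh), exact to round-off."""
    return math.tanh(ddg / (2.0 * R_KJ_PER_MOL_K * temperature))


def label_conversion(conversion: float, threshold: float = 0.8) -> str:
    """Binary reactivity class; the boundary value counts as 'high'."""
    return "high" if conversion >= threshold else "low"
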