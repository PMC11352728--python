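"""Reading and writing molecular structures, electronic sidecars and HTE tables.

Structures travel as plain XYZ files (the comment line may carry
``charge=<int>``), per-structure electronic properties as JSON "sidecars"
holding values ingested from single-point quantum-chemistry calculations,
and experimental outcomes as UTF-8 CSV tables. Atom indexing is 0-based
everywhere, including sidecars.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .periodic import COVALENT_RADII

__all__ = [
    "AtomicStructure",
    "ElectronicSidecar",
    "HTERecord",
    "ParseError",
    "ValidationError",
    "read_xyz",
    "write_xyz",
    "read_sidecar",
    "write_sidecar",
    "read_hte_table",
    "write_hte_table",
    "records_to_frame",
    "frame_to_records",
]

HTE_COLUMNS = [
    "ligand_id",
    "substrate_id",
    "solvent",
    "temperature",
    "pressure",
    "time",
    "conversion",
    "ee",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


@dataclass
class AtomicStructure:
    """One molecule or complex: element symbols plus Cartesian coordinates (A)."""

    id: str
    elements: list[str]
    coords: np.ndarray  # (n, 3) float array, Angstrom
    total_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(f"{self.id}: coords must be (n, 3), got {self.coords.shape}")
        if len(self.elements) != len(self.coords):
            raise ValidationError(
                f"{self.id}: {len(self.elements)} elements but {len(self.coords)} coordinates"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"{self.id}: non-finite coordinates")
        for el in self.elements:
            if el not in COVALENT_RADII:
                raise ValidationError(f"{self.id}: unsupported element {el!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def subset(self, indices: Sequence[int], new_id: str | None = None) -> "AtomicStructure":
        """New structure containing the given atoms, coordinates unchanged."""
        idx = list(indices)
        return AtomicStructure(
            id=new_id or self.id,
            elements=[self.elements[i] for i in idx],
            coords=self.coords[idx].copy(),
            total_charge=self.total_charge,
        )


@dataclass
class ElectronicSidecar:
    """Per-structure electronic properties from a single-point calculation.

    ``context`` distinguishes values computed on the intact [Rh(L)(NBD)]+
    complex from values computed on the extracted free ligand.
    """

    structure_id: str
    homo_lumo_gap: float  # eV
    context: str  # "complex" | "free_ligand"
    nbo_charge: dict[int, float] = field(default_factory=dict)  # atom index -> e
    lone_pair_occupancy: dict[int, float] = field(default_factory=dict)  # 0..2 electrons

    def __post_init__(self) -> None:
        if self.context not in ("complex", "free_ligand"):
            raise ValidationError(
                f"{self.structure_id}: context must be 'complex' or 'free_ligand', "
                f"got {self.context!r}"
            )
        if not math.isfinite(self.homo_lumo_gap):
            raise ValidationError(f"{self.structure_id}: non-finite HOMO-LUMO gap")
        self.nbo_charge = {int(k): float(v) for k, v in self.nbo_charge.items()}
        self.lone_pair_occupancy = {
            int(k): float(v) for k, v in self.lone_pair_occupancy.items()
        }
        for idx, occ in self.lone_pair_occupancy.items():
            if not 0.0 <= occ <= 2.0:
                raise ValidationError(
                    f"{self.structure_id}: lone-pair occupancy {occ} for atom {idx} "
                    "outside [0, 2]"
                )

    def check_against(self, structure: AtomicStructure) -> None:
        """Assert every referenced atom index exists in the paired structure."""
        n = structure.n_atoms
        for idx in list(self.nbo_charge) + list(self.lone_pair_occupancy):
            if not 0 <= idx < n:
                raise ValidationError(
                    f"{self.structure_id}: sidecar references atom {idx} but the "
                    f"structure has {n} atoms"
                )


@dataclass
class HTERecord:
    """One well of a 96-well hydrogenation plate."""

    ligand_id: str
    substrate_id: str
    solvent: str
    temperature: float  # K
    pressure: float  # bar
    time: float  # h
    conversion: float  # fraction in [0, 1]
    ee: float  # signed fraction in [-1, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion <= 1.0:
            raise ValidationError(f"conversion {self.conversion} outside [0, 1]")
        if abs(self.ee) > 1.0:
            raise ValidationError(f"|ee| = {abs(self.ee)} exceeds 1")


# ---------------------------------------------------------------------------
# XYZ


def read_xyz(path: str | Path) -> AtomicStructure:
    """Read one structure from a standard XYZ file.

    Line 1 is the atom count, line 2 a free comment which may carry a
    ``charge=<int>`` token; each following line is ``El x y z``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"{path}, line 1: malformed atom count {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    charge = 0
    for token in comment.split():
        if token.startswith("charge="):
            try:
                charge = int(token[len("charge="):])
            except ValueError:
                raise ParseError(f"{path}, line 2: malformed charge token {token!r}") from None
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) < n:
        raise ParseError(
            f"{path}: atom count says {n} but only {len(atom_lines)} atom lines present"
        )
    elements: list[str] = []
    coords = np.empty((n, 3))
    for i, ln in enumerate(atom_lines[:n]):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {i + 3}: expected 'El x y z', got {ln!r}")
        el = parts[0]
        if el not in COVALENT_RADII:
            raise ParseError(f"{path}, line {i + 3}: unknown element {el!r}")
        try:
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        except ValueError:
            raise ParseError(f"{path}, line {i + 3}: non-numeric coordinate in {ln!r}") from None
        elements.append(el)
    return AtomicStructure(id=path.stem, elements=elements, coords=coords, total_charge=charge)


def write_xyz(structure: AtomicStructure, path: str | Path, comment: str = "") -> None:
    """Write a structure as XYZ; the charge is stored on the comment line."""
    path = Path(path)
    parts = [comment.strip(), f"charge={structure.total_charge}"]
    comment_line = " ".join(p for p in parts if p)
    lines = [str(structure.n_atoms), comment_line]
    for el, (x, y, z) in zip(structure.elements, structure.coords):
        lines.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sidecars


def read_sidecar(path: str | Path) -> ElectronicSidecar:
    """Read and validate a JSON electronic sidecar."""
    path = Path(path)
    raw = json.loads(path.read_text())
    if "homo_lumo_gap" not in raw:
        raise ValidationError(f"{path}: missing required field 'homo_lumo_gap'")
    return ElectronicSidecar(
        structure_id=raw.get("structure_id", path.stem),
        homo_lumo_gap=float(raw["homo_lumo_gap"]),
        context=raw.get("context", "complex"),
        nbo_charge=raw.get("nbo_charge", {}),
        lone_pair_occupancy=raw.get("lone_pair_occupancy", {}),
    )


def write_sidecar(sidecar: ElectronicSidecar, path: str | Path) -> None:
    payload = {
        "structure_id": sidecar.structure_id,
        "homo_lumo_gap": sidecar.homo_lumo_gap,
        "context": sidecar.context,
        "nbo_charge": {str(k): v for k, v in sorted(sidecar.nbo_charge.items())},
        "lone_pair_occupancy": {
            str(k): v for k, v in sorted(sidecar.lone_pair_occupancy.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# HTE tables


def records_to_frame(records: Sequence[HTERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(r, c) for c in HTE_COLUMNS] for r in records], columns=HTE_COLUMNS
    )


def frame_to_records(frame: pd.DataFrame) -> list[HTERecord]:
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(HTERecord(**{c: getattr(row, c) for c in HTE_COLUMNS}))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def read_hte_table(path: str | Path) -> list[HTERecord]:
    """Read a CSV of HTE outcomes into validated records, row order preserved."""
    frame = pd.read_csv(
        path,
        dtype={"ligand_id": str, "substrate_id": str, "solvent": str},
        float_precision="round_trip",
    )
    missing = [c for c in HTE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return frame_to_records(frame)


def write_hte_table(records: Sequence[HTERecord], path: str | Path) -> None:
    """Write records as CSV with canonical float formatting (repr round-trip)."""
    frame = records_to_frame(records)
    frame.to_csv(path, index=False)
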