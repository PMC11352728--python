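"""The canonical 34-descriptor catalyst vector (S1-S15, G1-G8, E1-E11).

Each [Rh(L)(NBD)]+ precatalyst is summarized by 15 steric, 8 geometric and
11 electronic descriptors. The steric block holds percent buried volumes of
the ligand atoms with spheres centered on the metal, the max/min donor and
the donor midpoint at 3.5/4.5/6.0 A radii, the four quadrant values at the
metal (r = 3.5 A) and one hydrogen-excluded metal-centered value; S15 is
anchored to the min-donor-centered value at 3.5 A. The geometric block holds
the bite angle, exact cone angle, the NBD dihedral relative to the donors,
and metal-donor / donor-donor / metal-olefin-midpoint distances, with G4
anchored to d(Rh, min donor). The electronic block carries HOMO-LUMO gap,
donor and metal NBO charges and donor lone-pair occupancies from the complex
calculation (E5 = metal NBO charge) and from the free-ligand single point
(E7 = min-donor lone-pair occupancy, E10 = max-donor NBO charge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import AtomicStructure, ElectronicSidecar, read_sidecar, read_xyz
from .sterics import (
    BuriedVolumeSpec,
    bite_angle,
    buried_volume,
    distance,
    exact_cone_angle,
    nbd_dihedral,
    quadrant_buried_volume,
    _olefin_midpoints,
)
from .topology import (
    ComplexPartition,
    DonorAssignment,
    assign_donor_labels,
    build_graph,
    extract_free_ligand,
    partition_complex,
)

__all__ = [
    "DescriptorSpec",
    "SCHEMA",
    "CatalystDescriptors",
    "FeaturizationError",
    "schema_names",
    "category_counts",
    "featurize_catalyst",
    "featurize_library",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptorSpec:
    name: str
    category: str  # "steric" | "geometric" | "electronic"
    description: str


SCHEMA: list[DescriptorSpec] = [
    DescriptorSpec("S1", "steric", "%Vbur, ligand, metal center, r=3.5 A"),
    DescriptorSpec("S2", "steric", "%Vbur, ligand, metal center, r=4.5 A"),
    DescriptorSpec("S3", "steric", "%Vbur, ligand, metal center, r=6.0 A"),
    DescriptorSpec("S4", "steric", "%Vbur, ligand w/o H, metal center, r=3.5 A"),
    DescriptorSpec("S5", "steric", "%Vbur quadrant Q1, metal center, r=3.5 A"),
    DescriptorSpec("S6", "steric", "%Vbur quadrant Q2, metal center, r=3.5 A"),
    DescriptorSpec("S7", "steric", "%Vbur quadrant Q3, metal center, r=3.5 A"),
    DescriptorSpec("S8", "steric", "%Vbur quadrant Q4, metal center, r=3.5 A"),
    DescriptorSpec("S9", "steric", "%Vbur, ligand, max-donor center, r=3.5 A"),
    DescriptorSpec("S10", "steric", "%Vbur, ligand, max-donor center, r=4.5 A"),
    DescriptorSpec("S11", "steric", "%Vbur, ligand, max-donor center, r=6.0 A"),
    DescriptorSpec("S12", "steric", "%Vbur, ligand, donor-midpoint center, r=3.5 A"),
    DescriptorSpec("S13", "steric", "%Vbur, ligand, min-donor center, r=4.5 A"),
    DescriptorSpec("S14", "steric", "%Vbur, ligand, min-donor center, r=6.0 A"),
    DescriptorSpec("S15", "steric", "%Vbur, ligand, min-donor center, r=3.5 A"),
    DescriptorSpec("G1", "geometric", "bite angle donor-metal-donor (deg)"),
    DescriptorSpec("G2", "geometric", "exact cone angle of the ligand at the metal (deg)"),
    DescriptorSpec("G3", "geometric", "signed NBD dihedral vs the donor atoms (deg)"),
    DescriptorSpec("G4", "geometric", "distance metal - min donor (A)"),
    DescriptorSpec("G5", "geometric", "distance metal - max donor (A)"),
    DescriptorSpec("G6", "geometric", "distance min donor - max donor (A)"),
    DescriptorSpec("G7", "geometric", "distance metal - nearer olefin midpoint (A)"),
    DescriptorSpec("G8", "geometric", "distance metal - farther olefin midpoint (A)"),
    DescriptorSpec("E1", "electronic", "HOMO-LUMO gap of the complex (eV)"),
    DescriptorSpec("E2", "electronic", "NBO charge of the min donor, complex (e)"),
    DescriptorSpec("E3", "electronic", "NBO charge of the max donor, complex (e)"),
    DescriptorSpec("E4", "electronic", "lone-pair occupancy of the min donor, complex"),
    DescriptorSpec("E5", "electronic", "NBO charge of the metal center, complex (e)"),
    DescriptorSpec("E6", "electronic", "lone-pair occupancy of the max donor, complex"),
    DescriptorSpec("E7", "electronic", "lone-pair occupancy of the min donor, free ligand"),
    DescriptorSpec("E8", "electronic", "lone-pair occupancy of the max donor, free ligand"),
    DescriptorSpec("E9", "electronic", "NBO charge of the min donor, free ligand (e)"),
    DescriptorSpec("E10", "electronic", "NBO charge of the max donor, free ligand (e)"),
    DescriptorSpec("E11", "electronic", "HOMO-LUMO gap of the free ligand (eV)"),
]


def schema_names() -> list[str]:
    return [d.name for d in SCHEMA]


def category_counts() -> dict[str, int]:
    counts: dict[str, int] = {}
    for d in SCHEMA:
        counts[d.category] = counts.get(d.category, 0) + 1
    return counts


def descriptor_category(name: str) -> str:
    for d in SCHEMA:
        if d.name == name:
            return d.category
    raise KeyError(name)


@dataclass
class CatalystDescriptors:
    """The named, ordered 34-value feature vector of one precatalyst."""

    ligand_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        names = schema_names()
        missing = [n for n in names if n not in self.values]
        if missing:
            raise ValueError(f"{self.ligand_id}: missing descriptors {missing}")
        self.values = {n: float(self.values[n]) for n in names}
        bad = [n for n, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"{self.ligand_id}: non-finite descriptors {bad}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.ligand_id)


class FeaturizationError(RuntimeError):
    """A sub-descriptor failed; the message names the descriptor."""


def _quadrant_frame(
    structure: AtomicStructure,
    partition: ComplexPartition,
    donors: DonorAssignment,
) -> tuple[np.ndarray, np.ndarray]:
    """z along metal->donor-midpoint, xz-plane through the max donor.

    A monodentate ligand makes the max donor collinear with z; the lowest-
    index ligand atom at >15 degrees off-axis then serves as the xz reference.
    """
    metal_pos = structure.coords[partition.metal_index]
    midpoint = 0.5 * (
        structure.coords[donors.min_donor] + structure.coords[donors.max_donor]
    )
    z = midpoint - metal_pos
    xz = structure.coords[donors.max_donor] - metal_pos
    zn = z / np.linalg.norm(z)
    if np.linalg.norm(xz - np.dot(xz, zn) * zn) > 1e-6:
        return z, xz
    for i in sorted(partition.ligand_atoms):
        cand = structure.coords[i] - metal_pos
        n = np.linalg.norm(cand)
        if n < 1e-9:
            continue
        if np.degrees(np.arccos(np.clip(np.dot(cand / n, zn), -1, 1))) > 15.0:
            return z, cand
    raise ValueError("degenerate quadrant frame: all ligand atoms collinear with z-axis")


def featurize_catalyst(
    complex_structure: AtomicStructure,
    sidecar_complex: ElectronicSidecar,
    sidecar_free_ligand: ElectronicSidecar,
    metal_symbol: str = "Rh",
    grid_spacing: float = 0.05,
) -> CatalystDescriptors:
    """Assemble the full 34-descriptor vector for one precatalyst.

    Any failing sub-descriptor aborts with the descriptor name; no silent
    NaN ever enters the vector.
    """
    if sidecar_complex.context != "complex":
        raise ValueError("sidecar_complex must have context 'complex'")
    if sidecar_free_ligand.context != "free_ligand":
        raise ValueError("sidecar_free_ligand must have context 'free_ligand'")
    sidecar_complex.check_against(complex_structure)

    graph = build_graph(complex_structure)
    partition = partition_complex(complex_structure, graph, metal_symbol)
    donors = assign_donor_labels(partition, sidecar_complex)
    if donors.min_donor == donors.max_donor:
        logger.info(
            "%s: monodentate ligand, single donor fills both min/max roles",
            complex_structure.id,
        )
    free_ligand, mapping = extract_free_ligand(complex_structure, partition)
    sidecar_free_ligand.check_against(free_ligand)

    ligand = sorted(partition.ligand_atoms)
    metal = partition.metal_index
    metal_pos = complex_structure.coords[metal]
    min_pos = complex_structure.coords[donors.min_donor]
    max_pos = complex_structure.coords[donors.max_donor]
    mid_pos = 0.5 * (min_pos + max_pos)

    values: dict[str, float] = {}

    def compute(name: str, fn):
        try:
            values[name] = float(fn())
        except Exception as exc:
            raise FeaturizationError(f"descriptor {name} failed: {exc}") from exc

    def vbur(center, r, include_h=True):
        spec = BuriedVolumeSpec(
            center=center,
            sphere_radius=r,
            include_hydrogens=include_h,
            grid_spacing=grid_spacing,
        )
        return buried_volume(complex_structure, ligand, spec)

    compute("S1", lambda: vbur(metal_pos, 3.5))
    compute("S2", lambda: vbur(metal_pos, 4.5))
    compute("S3", lambda: vbur(metal_pos, 6.0))
    compute("S4", lambda: vbur(metal_pos, 3.5, include_h=False))

    def quadrants():
        z, xz = _quadrant_frame(complex_structure, partition, donors)
        spec = BuriedVolumeSpec(
            center=metal_pos, sphere_radius=3.5, grid_spacing=grid_spacing
        )
        return quadrant_buried_volume(complex_structure, ligand, spec, z, xz)

    try:
        quad = quadrants()
    except Exception as exc:
        raise FeaturizationError(f"descriptor S5-S8 (quadrants) failed: {exc}") from exc
    for i, q in enumerate(("Q1", "Q2", "Q3", "Q4"), start=5):
        values[f"S{i}"] = float(quad[q])

    compute("S9", lambda: vbur(max_pos, 3.5))
    compute("S10", lambda: vbur(max_pos, 4.5))
    compute("S11", lambda: vbur(max_pos, 6.0))
    compute("S12", lambda: vbur(mid_pos, 3.5))
    compute("S13", lambda: vbur(min_pos, 4.5))
    compute("S14", lambda: vbur(min_pos, 6.0))
    compute("S15", lambda: vbur(min_pos, 3.5))

    compute("G1", lambda: bite_angle(complex_structure, metal, donors.min_donor, donors.max_donor)
            if donors.min_donor != donors.max_donor else 0.0)
    compute("G2", lambda: exact_cone_angle(complex_structure, metal, ligand).angle)
    compute("G3", lambda: nbd_dihedral(complex_structure, partition, donors))
    compute("G4", lambda: distance(complex_structure, metal, donors.min_donor))
    compute("G5", lambda: distance(complex_structure, metal, donors.max_donor))
    compute("G6", lambda: distance(complex_structure, donors.min_donor, donors.max_donor))

    def olefin_distances():
        mids = _olefin_midpoints(complex_structure, partition.auxiliary_atoms, metal)
        d = sorted(float(np.linalg.norm(m - metal_pos)) for m in mids)
        return d

    try:
        d_olefin = olefin_distances()
    except Exception as exc:
        raise FeaturizationError(f"descriptor G7/G8 failed: {exc}") from exc
    values["G7"], values["G8"] = d_olefin

    def charge(sidecar: ElectronicSidecar, idx: int) -> float:
        if idx not in sidecar.nbo_charge:
            raise KeyError(f"no NBO charge for atom {idx} in {sidecar.structure_id}")
        return sidecar.nbo_charge[idx]

    def occupancy(sidecar: ElectronicSidecar, idx: int) -> float:
        if idx not in sidecar.lone_pair_occupancy:
            raise KeyError(f"no lone-pair occupancy for atom {idx} in {sidecar.structure_id}")
        return sidecar.lone_pair_occupancy[idx]

    fmin, fmax = mapping[donors.min_donor], mapping[donors.max_donor]
    compute("E1", lambda: sidecar_complex.homo_lumo_gap)
    compute("E2", lambda: charge(sidecar_complex, donors.min_donor))
    compute("E3", lambda: charge(sidecar_complex, donors.max_donor))
    compute("E4", lambda: occupancy(sidecar_complex, donors.min_donor))
    compute("E5", lambda: charge(sidecar_complex, metal))
    compute("E6", lambda: occupancy(sidecar_complex, donors.max_donor))
    compute("E7", lambda: occupancy(sidecar_free_ligand, fmin))
    compute("E8", lambda: occupancy(sidecar_free_ligand, fmax))
    compute("E9", lambda: charge(sidecar_free_ligand, fmin))
    compute("E10", lambda: charge(sidecar_free_ligand, fmax))
    compute("E11", lambda: sidecar_free_ligand.homo_lumo_gap)

    return CatalystDescriptors(ligand_id=complex_structure.id, values=values)


def featurize_library(
    manifest: dict[str, dict[str, str]] | str | Path,
    grid_spacing: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Featurize a whole ligand library from a manifest.

    The manifest (dict or YAML path) maps ligand_id to the three files
    ``complex_xyz``, ``sidecar_complex`` and ``sidecar_free_ligand``.
    Returns (descriptor table in schema column order, failure table); a
    failing ligand lands in the failure table instead of aborting the batch.
    """
    if not isinstance(manifest, dict):
        manifest = yaml.safe_load(Path(manifest).read_text())
    rows: list[pd.Series] = []
    failures: list[dict[str, str]] = []
    for ligand_id in manifest:
        entry = manifest[ligand_id]
        try:
            structure = read_xyz(entry["complex_xyz"])
            structure.id = str(ligand_id)
            desc = featurize_catalyst(
                structure,
                read_sidecar(entry["sidecar_complex"]),
                read_sidecar(entry["sidecar_free_ligand"]),
                grid_spacing=grid_spacing,
            )
            rows.append(desc.as_series())
        except Exception as exc:
            logger.error("featurization failed for %s: %s", ligand_id, exc)
            failures.append({"ligand_id": str(ligand_id), "error": str(exc)})
    table = pd.DataFrame(rows, columns=schema_names())
    table.index.name = "ligand_id"
    return table, pd.DataFrame(failures, columns=["ligand_id", "error"])
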