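"""Steric fingerprints of prochiral olefin substrates.

The fingerprint describes the local steric environment of the C=C bond:
a buried volume around each of the six enumerated atoms (the two olefin
carbons C1/C2 and the four substituent anchors R1-R4) plus sterimol
B1/B5/L for each of the four C-R pairings — 18 values in total. Substrate
geometries come either from an externally optimized XYZ file or from a
seeded distance-geometry embedding of a SMILES string.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import AtomicStructure
from .periodic import ATOMIC_NUMBERS
from .sterics import BuriedVolumeSpec, buried_volume, sterimol
from .topology import MolecularGraph, build_graph

__all__ = [
    "OlefinSite",
    "SubstrateFingerprint",
    "DOUBLE_BOND_CC_CUTOFF",
    "locate_olefin",
    "substrate_fingerprint",
    "embed_from_smiles",
    "fingerprint_names",
]

#: a C-C contact at or below this length (A) is treated as a double bond
DOUBLE_BOND_CC_CUTOFF = 1.40


@dataclass
class OlefinSite:
    """The olefin carbons and their four substituent anchors.

    R1, R2 hang off C1 and R3, R4 off C2; per carbon the anchors are
    ordered by descending atomic number, then ascending atom index, with
    hydrogens counting as substituents.
    """

    C1: int
    C2: int
    R: list[int]  # [R1, R2, R3, R4]


@dataclass
class SubstrateFingerprint:
    """6 buried volumes + 12 sterimol parameters, in canonical order."""

    vbur: dict[str, float]  # keys C1, C2, R1..R4
    sterimol: dict[str, float]  # keys like C1R1_B1, C1R1_B5, C1R1_L, ...

    def as_series(self, name: str | None = None) -> pd.Series:
        data = {f"vbur_{k}": v for k, v in self.vbur.items()}
        data.update(self.sterimol)
        return pd.Series(data, name=name)


def fingerprint_names() -> list[str]:
    names = [f"vbur_{k}" for k in ("C1", "C2", "R1", "R2", "R3", "R4")]
    for c, rs in (("C1", ("R1", "R2")), ("C2", ("R3", "R4"))):
        for r in rs:
            for p in ("B1", "B5", "L"):
                names.append(f"{c}{r}_{p}")
    return names


def _ordered_substituents(
    structure: AtomicStructure, graph: MolecularGraph, carbon: int, other: int
) -> list[int]:
    subs = [n for n in graph.neighbors(carbon) if n != other]
    if len(subs) != 2:
        raise ValueError(
            f"olefin carbon {carbon} has {len(subs)} substituents, expected 2"
        )
    return sorted(subs, key=lambda i: (-ATOMIC_NUMBERS[structure.elements[i]], i))


def locate_olefin(
    structure: AtomicStructure,
    graph: MolecularGraph | None = None,
    hint: tuple[int, int] | None = None,
) -> OlefinSite:
    """Find the C=C bond and enumerate its substituent anchors.

    Candidates are bonded carbon pairs at double-bond distance
    (<= ``DOUBLE_BOND_CC_CUTOFF``); an explicit (C1, C2) ``hint`` resolves
    ambiguous inputs such as dienes.
    """
    if graph is None:
        graph = build_graph(structure)
    if hint is not None:
        c1, c2 = hint
    else:
        candidates = []
        for i, j in sorted(graph.edges):
            if structure.elements[i] == "C" and structure.elements[j] == "C":
                if np.linalg.norm(structure.coords[i] - structure.coords[j]) <= DOUBLE_BOND_CC_CUTOFF:
                    candidates.append((i, j))
        if not candidates:
            raise ValueError("no C=C candidate found and no hint given")
        if len(candidates) > 1:
            raise ValueError(
                f"ambiguous olefin: {len(candidates)} C=C candidates {candidates}; "
                "pass an explicit hint"
            )
        c1, c2 = candidates[0]
    if (min(c1, c2), max(c1, c2)) not in graph.edges:
        raise ValueError(f"hinted atoms {c1}, {c2} are not bonded")
    r12 = _ordered_substituents(structure, graph, c1, c2)
    r34 = _ordered_substituents(structure, graph, c2, c1)
    return OlefinSite(C1=c1, C2=c2, R=r12 + r34)


def _branch_atoms(graph: MolecularGraph, start: int, blocked: int) -> set[int]:
    """Atoms reachable from ``start`` without crossing ``blocked``."""
    g = graph.to_networkx()
    g.remove_node(blocked)
    return set(nx.node_connected_component(g, start))


def substrate_fingerprint(
    structure: AtomicStructure,
    site: OlefinSite,
    graph: MolecularGraph | None = None,
    grid_spacing: float = 0.05,
) -> SubstrateFingerprint:
    """Compute the 18-value steric fingerprint of one substrate.

    Buried volumes use a 3.5 A sphere on each enumerated atom with the whole
    molecule minus the center atom as the occupying set; sterimol for the
    pairing (Ci, Rj) uses the branch reachable from Rj without crossing Ci.
    """
    if graph is None:
        graph = build_graph(structure)
    all_atoms = set(range(structure.n_atoms))
    centers = {"C1": site.C1, "C2": site.C2}
    centers.update({f"R{k + 1}": idx for k, idx in enumerate(site.R)})
    vbur = {}
    for label, idx in centers.items():
        spec = BuriedVolumeSpec(center=idx, sphere_radius=3.5, grid_spacing=grid_spacing)
        vbur[label] = buried_volume(structure, all_atoms - {idx}, spec)
    ster = {}
    pairings = [
        ("C1", "R1", site.C1, site.R[0]),
        ("C1", "R2", site.C1, site.R[1]),
        ("C2", "R3", site.C2, site.R[2]),
        ("C2", "R4", site.C2, site.R[3]),
    ]
    for cl, rl, c_idx, r_idx in pairings:
        branch = _branch_atoms(graph, r_idx, c_idx)
        res = sterimol(structure, attach=c_idx, first=r_idx, atom_subset=branch)
        ster[f"{cl}{rl}_B1"] = res.B1
        ster[f"{cl}{rl}_B5"] = res.B5
        ster[f"{cl}{rl}_L"] = res.L
    return SubstrateFingerprint(vbur=vbur, sterimol=ster)


def embed_from_smiles(smiles: str, seed: int = 0, optimize: bool = True) -> AtomicStructure:
    """Deterministic 3D conformer from SMILES.

    Distance-geometry (ETKDG) embedding with explicit hydrogens and, by
    default, an MMFF94 relaxation; the same seed reproduces identical
    coordinates. ``optimize=False`` gives the raw embedded geometry, which
    mimics a quick generator-level structure as opposed to a refined one.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError(f"3D embedding failed for {smiles!r}")
    if optimize:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    conf = mol.GetConformer()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    charge = Chem.GetFormalCharge(mol)
    return AtomicStructure(id=smiles, elements=elements, coords=coords, total_charge=charge)
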