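"""Bond perception and graph-based partitioning of [M(L)(diene)]+ complexes.

A bonding graph is perceived from interatomic distances against scaled
covalent radii. Deleting the metal then splits the complex into connected
components: the component(s) carrying a P or N atom coordinated to the metal
form the ligand, and the all-carbon metal-bound component is the auxiliary
diene (NBD in the precatalysts studied here). For non-symmetric bidentate
ligands the two coordinating atoms are told apart by their partial charge:
"max donor" is the most positively charged one, "min donor" the least.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import AtomicStructure, ElectronicSidecar
from .periodic import covalent_radius

__all__ = [
    "MolecularGraph",
    "ComplexPartition",
    "DonorAssignment",
    "TopologyError",
    "build_graph",
    "partition_complex",
    "assign_donor_labels",
    "extract_free_ligand",
]

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 1.20
#: explicit cutoff for "coordinated to the metal" (covers Rh-P/Rh-N with margin)
METAL_DONOR_CUTOFF = 2.8
DONOR_ELEMENTS = ("P", "N")


class TopologyError(ValueError):
    """The complex topology does not match the expected [M(L)(diene)] layout."""


@dataclass
class MolecularGraph:
    """Undirected bonding graph over atom indices."""

    n_atoms: int
    edges: set[tuple[int, int]]

    def __post_init__(self) -> None:
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge on atom {i}")
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"edge ({i},{j}) out of range for {self.n_atoms} atoms")
            canon.add((min(i, j), max(i, j)))
        self.edges = canon

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.edges)
        return g

    def neighbors(self, i: int) -> list[int]:
        return sorted(j if a == i else a for a, j in self.edges if i in (a, j))


@dataclass
class ComplexPartition:
    """Metal / donor / ligand / auxiliary-diene atom index sets."""

    metal_index: int
    donor_indices: list[int]
    ligand_atoms: set[int] = field(default_factory=set)
    auxiliary_atoms: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.ligand_atoms & self.auxiliary_atoms:
            raise TopologyError("ligand and auxiliary atom sets overlap")
        if self.metal_index in self.ligand_atoms or self.metal_index in self.auxiliary_atoms:
            raise TopologyError("metal listed among ligand/auxiliary atoms")
        for d in self.donor_indices:
            if d not in self.ligand_atoms:
                raise TopologyError(f"donor atom {d} not part of the ligand")


@dataclass
class DonorAssignment:
    """min/max donor = least/most positively charged coordinating atom."""

    min_donor: int
    max_donor: int


def build_graph(structure: AtomicStructure, scale: float = DEFAULT_SCALE) -> MolecularGraph:
    """Perceive bonds: edge (i,j) iff dist <= scale * (r_cov(i) + r_cov(j))."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    radii = np.array([covalent_radius(el) for el in structure.elements])
    if structure.n_atoms < 2:
        return MolecularGraph(structure.n_atoms, set())
    dist = squareform(pdist(structure.coords))
    cutoff = scale * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    return MolecularGraph(structure.n_atoms, {(int(i), int(j)) for i, j in zip(ii, jj)})


def partition_complex(
    structure: AtomicStructure,
    graph: MolecularGraph,
    metal_symbol: str = "Rh",
) -> ComplexPartition:
    """Split a [M(L)(diene)]+ complex into metal, ligand and auxiliary atoms.

    The metal is deleted from the graph; every remaining component holding a
    P/N atom within ``METAL_DONOR_CUTOFF`` of the metal joins the ligand
    (multiple such components are unioned and a warning logged), the
    metal-bound all-carbon component is the auxiliary diene, and anything
    else bound to the metal raises rather than guessing.
    """
    metal_candidates = [i for i, el in enumerate(structure.elements) if el == metal_symbol]
    if len(metal_candidates) != 1:
        raise TopologyError(
            f"expected exactly one {metal_symbol} atom, found {len(metal_candidates)}"
        )
    metal = metal_candidates[0]

    g = graph.to_networkx()
    metal_neighbors = set(g.neighbors(metal))
    g.remove_node(metal)

    dist_to_metal = np.linalg.norm(structure.coords - structure.coords[metal], axis=1)
    donors = [
        i
        for i, el in enumerate(structure.elements)
        if el in DONOR_ELEMENTS and i != metal and dist_to_metal[i] <= METAL_DONOR_CUTOFF
    ]

    ligand_atoms: set[int] = set()
    auxiliary_atoms: set[int] = set()
    ligand_components = 0
    for comp in nx.connected_components(g):
        comp_donors = [d for d in donors if d in comp]
        if comp_donors:
            ligand_atoms |= comp
            ligand_components += 1
            continue
        if comp & metal_neighbors:
            heavy = {i for i in comp if structure.elements[i] != "H"}
            if heavy and all(structure.elements[i] == "C" for i in heavy):
                auxiliary_atoms |= comp
            else:
                symbols = sorted({structure.elements[i] for i in comp})
                raise TopologyError(
                    f"metal-bound component with elements {symbols} is neither a donor "
                    "ligand nor an all-carbon diene"
                )
        else:
            # a free-floating fragment (e.g. counter-ion) is unexpected here
            raise TopologyError("component not bonded to the metal at all")
    if not ligand_atoms:
        raise TopologyError("no donor ligand found")
    if ligand_components > 1:
        logger.warning(
            "ligand fragmented into %d components after metal removal; unioning them",
            ligand_components,
        )
    donors_in_ligand = sorted(d for d in donors if d in ligand_atoms)
    return ComplexPartition(
        metal_index=metal,
        donor_indices=donors_in_ligand,
        ligand_atoms=ligand_atoms,
        auxiliary_atoms=auxiliary_atoms,
    )


def assign_donor_labels(
    partition: ComplexPartition, sidecar_complex: ElectronicSidecar
) -> DonorAssignment:
    """Label donors by NBO charge; ties go to the smaller atom index.

    For a monodentate ligand the single donor fills both roles.
    """
    charges = {}
    for d in partition.donor_indices:
        if d not in sidecar_complex.nbo_charge:
            raise ValueError(f"missing NBO charge for donor atom {d}")
        charges[d] = sidecar_complex.nbo_charge[d]
    # sort ascending by (charge, index): first entry = min donor, last = max
    ranked = sorted(charges, key=lambda d: (charges[d], d))
    return DonorAssignment(min_donor=ranked[0], max_donor=ranked[-1])


def extract_free_ligand(
    structure: AtomicStructure, partition: ComplexPartition
) -> tuple[AtomicStructure, dict[int, int]]:
    """Cut the ligand out of the complex, coordinates untouched.

    Returns the free-ligand structure and the old->new index mapping, so
    sidecars computed on the extracted geometry can be cross-referenced.
    """
    old_indices = sorted(partition.ligand_atoms)
    mapping = {old: new for new, old in enumerate(old_indices)}
    ligand = structure.subset(old_indices, new_id=f"{structure.id}_free_ligand")
    ligand.total_charge = 0  # the +1 charge lives on the complex, not the free ligand
    return ligand, mapping
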