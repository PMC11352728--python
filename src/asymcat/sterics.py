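"""Steric and geometric descriptors of organometallic fragments.

Implements the primitives behind the catalyst and substrate feature sets:

* percent buried volume (%Vbur) — share of a probe sphere occupied by the
  scaled van der Waals spheres of a chosen atom set, on a deterministic
  cubic grid; also resolved per quadrant in a user-supplied frame,
* the exact cone angle — the minimal apex angle of a cone at the metal
  containing every atom sphere, found by optimizing the cone axis,
* sterimol L / B1 / B5 of a substituent relative to an attachment axis,
* bite angle, four-point signed dihedral, distances and centroids.

Radii conventions (documented package constants): %Vbur uses Bondi van der
Waals radii scaled by 1.17 with hydrogens included, sphere radius 3.5 A and
grid spacing 0.05 A by default; the cone angle uses unscaled Bondi radii;
sterimol uses unscaled Bondi radii with hydrogen at 1.10 A, the classic
Verloop choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .io import AtomicStructure
from .periodic import VDW_RADII, vdw_radius

__all__ = [
    "BuriedVolumeSpec",
    "SterimolResult",
    "ConeAngleResult",
    "STERIMOL_RADII",
    "buried_volume",
    "quadrant_buried_volume",
    "exact_cone_angle",
    "sterimol",
    "bite_angle",
    "dihedral_4pt",
    "nbd_dihedral",
    "distance",
    "centroid",
]

#: Verloop-style radii: Bondi with hydrogen at 1.10 A, unscaled.
STERIMOL_RADII: dict[str, float] = {**VDW_RADII, "H": 1.10}


@dataclass
class BuriedVolumeSpec:
    """Parameters of one %Vbur evaluation.

    ``center`` is either an atom index or an explicit 3-vector.
    """

    center: int | np.ndarray
    sphere_radius: float = 3.5
    radii_scale: float = 1.17
    include_hydrogens: bool = True
    excluded_atoms: frozenset[int] = field(default_factory=frozenset)
    grid_spacing: float = 0.05

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.radii_scale <= 0:
            raise ValueError("radii_scale must be positive")
        self.excluded_atoms = frozenset(self.excluded_atoms)

    def resolve_center(self, structure: AtomicStructure) -> np.ndarray:
        if isinstance(self.center, (int, np.integer)):
            return structure.coords[int(self.center)]
        return np.asarray(self.center, dtype=float)


@dataclass
class SterimolResult:
    L: float
    B1: float
    B5: float


@dataclass
class ConeAngleResult:
    angle: float  # degrees
    axis: np.ndarray  # unit vector from the apex


def _effective_atoms(
    structure: AtomicStructure,
    atom_subset: Iterable[int],
    spec: BuriedVolumeSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and scaled radii of the occupying atoms after filtering."""
    subset = [
        i
        for i in atom_subset
        if i not in spec.excluded_atoms
        and (spec.include_hydrogens or structure.elements[i] != "H")
    ]
    if not subset:
        return np.empty((0, 3)), np.empty(0)
    positions = structure.coords[subset]
    radii = np.array([vdw_radius(structure.elements[i]) for i in subset]) * spec.radii_scale
    return positions, radii


def _occupancy_grid(
    center: np.ndarray,
    sphere_radius: float,
    spacing: float,
    positions: np.ndarray,
    radii: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean occupancy over a cubic grid clipped to the probe sphere.

    Returns (occupied, inside_sphere, axis) where ``axis`` holds the grid
    offsets relative to the center along each Cartesian direction. Atoms are
    rasterized one by one into their bounding sub-boxes, which keeps the
    cost proportional to atom volume rather than sphere volume.
    """
    n = int(math.ceil(sphere_radius / spacing))
    axis = np.arange(-n, n + 1) * spacing
    m = axis.size
    sq = axis**2
    inside = sq[:, None, None] + sq[None, :, None] + sq[None, None, :] <= sphere_radius**2
    occupied = np.zeros((m, m, m), dtype=bool)
    for pos, r in zip(positions, radii):
        rel = pos - center
        if np.linalg.norm(rel) > sphere_radius + r:
            continue
        lo = np.maximum(0, np.searchsorted(axis, rel - r, side="left"))
        hi = np.minimum(m, np.searchsorted(axis, rel + r, side="right"))
        if np.any(lo >= hi):
            continue
        dx = axis[lo[0]:hi[0]] - rel[0]
        dy = axis[lo[1]:hi[1]] - rel[1]
        dz = axis[lo[2]:hi[2]] - rel[2]
        ball = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
            <= r**2
        )
        occupied[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ball
    return occupied, inside, axis


def buried_volume(
    structure: AtomicStructure,
    atom_subset: Iterable[int],
    spec: BuriedVolumeSpec,
) -> float:
    """Percent of the probe sphere buried by the scaled vdW spheres of a subset."""
    positions, radii = _effective_atoms(structure, atom_subset, spec)
    if positions.shape[0] == 0:
        return 0.0
    center = spec.resolve_center(structure)
    occupied, inside, _ = _occupancy_grid(
        center, spec.sphere_radius, spec.grid_spacing, positions, radii
    )
    return 100.0 * float(np.count_nonzero(occupied & inside)) / float(np.count_nonzero(inside))


def quadrant_buried_volume(
    structure: AtomicStructure,
    atom_subset: Iterable[int],
    spec: BuriedVolumeSpec,
    z_axis: np.ndarray,
    xz_vector: np.ndarray,
) -> dict[str, float]:
    """%Vbur resolved into the four xy-quadrants of a right-handed frame.

    The frame has +z along ``z_axis`` and the xz-plane containing
    ``xz_vector`` (conventionally metal->donor-midpoint and the max donor).
    Quadrant keys are Q1 (+x,+y), Q2 (-x,+y), Q3 (-x,-y), Q4 (+x,-y); the
    mean of the four equals the total %Vbur up to grid-partition jitter.
    """
    z_axis = np.asarray(z_axis, dtype=float)
    xz_vector = np.asarray(xz_vector, dtype=float)
    nz = np.linalg.norm(z_axis)
    if nz < 1e-9:
        raise ValueError("degenerate frame: zero z-axis")
    ez = z_axis / nz
    ex = xz_vector - np.dot(xz_vector, ez) * ez
    nx_ = np.linalg.norm(ex)
    if nx_ < 1e-9:
        raise ValueError("degenerate frame: xz-vector collinear with z-axis")
    ex /= nx_
    ey = np.cross(ez, ex)

    positions, radii = _effective_atoms(structure, atom_subset, spec)
    center = spec.resolve_center(structure)
    occupied, inside, axis = _occupancy_grid(
        center, spec.sphere_radius, spec.grid_spacing, positions, radii
    )
    m = axis.size
    gx = np.broadcast_to(axis[:, None, None], (m, m, m))
    gy = np.broadcast_to(axis[None, :, None], (m, m, m))
    gz = np.broadcast_to(axis[None, None, :], (m, m, m))
    # frame coordinates of every grid offset
    fx = gx * ex[0] + gy * ex[1] + gz * ex[2]
    fy = gx * ey[0] + gy * ey[1] + gz * ey[2]
    quadrant_masks = {
        "Q1": (fx >= 0) & (fy >= 0),
        "Q2": (fx < 0) & (fy >= 0),
        "Q3": (fx < 0) & (fy < 0),
        "Q4": (fx >= 0) & (fy < 0),
    }
    out = {}
    for name, qmask in quadrant_masks.items():
        denom = np.count_nonzero(inside & qmask)
        num = np.count_nonzero(occupied & inside & qmask)
        out[name] = 100.0 * num / denom if denom else 0.0
    return out


# ---------------------------------------------------------------------------
# Exact cone angle


def _cone_half_angle(axis: np.ndarray, units: np.ndarray, betas: np.ndarray) -> float:
    """Required cone half-angle about ``axis`` (radians)."""
    cosines = np.clip(units @ axis, -1.0, 1.0)
    return float(np.max(np.arccos(cosines) + betas))


def exact_cone_angle(
    structure: AtomicStructure,
    apex: int,
    atom_subset: Iterable[int],
    radii: Mapping[str, float] | None = None,
    n_seed_axes: int = 4096,
) -> ConeAngleResult:
    """Minimal apex angle of a cone at ``apex`` containing every atom sphere.

    The axis is optimized over a Fibonacci-sphere seed grid followed by
    derivative-free local refinement; unscaled Bondi radii by default.
    """
    subset = [i for i in atom_subset if i != apex]
    if not subset:
        raise ValueError("empty atom subset")
    table = radii if radii is not None else VDW_RADII
    apex_pos = structure.coords[apex]
    rel = structure.coords[subset] - apex_pos
    dists = np.linalg.norm(rel, axis=1)
    rads = np.array([table[structure.elements[i]] for i in subset])
    if np.any(dists <= rads):
        bad = subset[int(np.argmax(rads - dists))]
        raise ValueError(f"cone undefined: sphere of atom {bad} engulfs the apex")
    units = rel / dists[:, None]
    betas = np.arcsin(rads / dists)

    # Fibonacci-sphere seeds
    k = np.arange(n_seed_axes)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    zc = 1.0 - 2.0 * (k + 0.5) / n_seed_axes
    rc = np.sqrt(1.0 - zc**2)
    seeds = np.stack([rc * np.cos(phi), rc * np.sin(phi), zc], axis=1)
    half = np.arccos(np.clip(seeds @ units.T, -1, 1)) + betas[None, :]
    worst = half.max(axis=1)
    best = seeds[int(np.argmin(worst))]

    # local refinement in spherical coordinates about the best seed
    theta0 = math.acos(np.clip(best[2], -1, 1))
    phi0 = math.atan2(best[1], best[0])

    def objective(x: np.ndarray) -> float:
        th, ph = x
        ax = np.array(
            [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
        )
        return _cone_half_angle(ax, units, betas)

    res = minimize(
        objective,
        x0=[theta0, phi0],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    th, ph = res.x
    axis = np.array([math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)])
    return ConeAngleResult(angle=math.degrees(2.0 * res.fun), axis=axis)


# ---------------------------------------------------------------------------
# Sterimol


def sterimol(
    structure: AtomicStructure,
    attach: int,
    first: int,
    atom_subset: Iterable[int],
    radii: Mapping[str, float] | None = None,
    scan_step_deg: float = 0.1,
) -> SterimolResult:
    """Sterimol L, B1, B5 of a substituent along the attach->first axis.

    L is the maximal axial extent measured from the attachment atom, B5 the
    maximal and B1 the minimal width perpendicular to the axis; B1 is found
    by a rotational scan of supporting half-planes in ``scan_step_deg``
    increments.
    """
    subset = [i for i in atom_subset if i != attach]
    if not subset:
        raise ValueError("empty substituent subset")
    table = radii if radii is not None else STERIMOL_RADII
    origin = structure.coords[attach]
    axis_vec = structure.coords[first] - origin
    norm = np.linalg.norm(axis_vec)
    if norm < 1e-9:
        raise ValueError("zero-length attachment axis")
    u = axis_vec / norm

    rel = structure.coords[subset] - origin
    rads = np.array([table[structure.elements[i]] for i in subset])
    proj = rel @ u
    perp_vec = rel - proj[:, None] * u
    perp = np.linalg.norm(perp_vec, axis=1)

    L = float(np.max(proj + rads))
    B5 = float(np.max(perp + rads))

    # orthonormal basis perpendicular to the axis (deterministic choice)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    angles = np.deg2rad(np.arange(0.0, 360.0, scan_step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (k, 2)
    comp = np.stack([perp_vec @ e1, perp_vec @ e2], axis=1)  # (n, 2)
    widths = comp @ dirs.T + rads[:, None]  # (n, k)
    B1 = float(np.min(widths.max(axis=0)))
    return SterimolResult(L=L, B1=B1, B5=B5)


# ---------------------------------------------------------------------------
# Angles and distances


def bite_angle(structure: AtomicStructure, metal: int, donor_a: int, donor_b: int) -> float:
    """Donor-metal-donor angle in degrees, in (0, 180]."""
    va = structure.coords[donor_a] - structure.coords[metal]
    vb = structure.coords[donor_b] - structure.coords[metal]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-9 or nb < 1e-9:
        raise ValueError("coincident atoms in bite-angle computation")
    return math.degrees(math.acos(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)))


def dihedral_4pt(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC convention, (-180, 180]."""
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate (collinear) points in dihedral")
    m1 = np.cross(n1, b2 / nb2)
    angle = math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    return 180.0 if angle == -180.0 else angle


def _olefin_midpoints(
    structure: AtomicStructure,
    auxiliary_atoms: Iterable[int],
    metal: int,
    bond_scale: float = 1.20,
) -> list[np.ndarray]:
    """Midpoints of the two metal-facing auxiliary C-C pairs.

    Candidate pairs are bonded auxiliary carbon pairs ranked by midpoint
    distance to the metal (atom-index tie-break); the two nearest disjoint
    pairs are taken as the coordinating olefins.
    """
    from .periodic import covalent_radius

    aux = sorted(
        i for i in auxiliary_atoms if structure.elements[i] == "C"
    )
    pairs = []
    for ai, i in enumerate(aux):
        for j in aux[ai + 1:]:
            d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
            if d <= bond_scale * (covalent_radius("C") * 2):
                mid = 0.5 * (structure.coords[i] + structure.coords[j])
                dist = float(np.linalg.norm(mid - structure.coords[metal]))
                pairs.append((round(dist, 9), i, j, mid))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    chosen: list[tuple[int, int, np.ndarray]] = []
    used: set[int] = set()
    for _, i, j, mid in pairs:
        if i in used or j in used:
            continue
        chosen.append((i, j, mid))
        used |= {i, j}
        if len(chosen) == 2:
            break
    if len(chosen) < 2:
        raise ValueError("could not identify two metal-facing olefin midpoints")
    return [c[2] for c in chosen]


def nbd_dihedral(
    structure: AtomicStructure,
    partition,
    donors,
) -> float:
    """Signed dihedral min_donor - metal - olefin-midpoint-1 - olefin-midpoint-2.

    Orients the diene (NBD) relative to the donor plane; the sign flips for
    mirror-image complexes. The two midpoints (often equidistant from the
    metal) are ordered by distance to the min donor — a purely geometric
    rule, so the value is invariant under atom renumbering.
    """
    mids = _olefin_midpoints(structure, partition.auxiliary_atoms, partition.metal_index)
    anchor = structure.coords[donors.min_donor]
    mids = sorted(mids, key=lambda m: round(float(np.linalg.norm(m - anchor)), 9))
    return dihedral_4pt(
        anchor,
        structure.coords[partition.metal_index],
        mids[0],
        mids[1],
    )


def distance(structure: AtomicStructure, i: int, j: int) -> float:
    return float(np.linalg.norm(structure.coords[i] - structure.coords[j]))


def centroid(structure: AtomicStructure, indices: Sequence[int]) -> np.ndarray:
    idx = list(indices)
    if not idx:
        raise ValueError("centroid of empty index set")
    return structure.coords[idx].mean(axis=0)
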