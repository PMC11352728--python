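"""Steric/geometric descriptor oracles: closed forms, brute force, Monte Carlo."""

import math

import numpy as np
import pytest

from asymcat.io import AtomicStructure
from asymcat.periodic import VDW_RADII
from asymcat.sterics import (
    STERIMOL_RADII,
    BuriedVolumeSpec,
    bite_angle,
    buried_volume,
    centroid,
    dihedral_4pt,
    distance,
    exact_cone_angle,
    quadrant_buried_volume,
    sterimol,
)


def _structure(elements, coords):
    return AtomicStructure(id="t", elements=elements, coords=np.array(coords, float))


def _rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()


class TestBuriedVolume:
    def test_empty_subset_is_zero(self):
        s = _structure(["Rh"], [[0, 0, 0]])
        assert buried_volume(s, [], BuriedVolumeSpec(center=0)) == 0.0

    def test_single_atom_closed_form(self):
        # one carbon at the sphere center, radii scaled so r_atom = 2.0 A:
        # buried share = (2.0 / 3.5)^3 = 18.66%
        s = _structure(["C"], [[0, 0, 0]])
        spec = BuriedVolumeSpec(
            center=np.zeros(3), sphere_radius=3.5, radii_scale=2.0 / VDW_RADII["C"]
        )
        expected = 100.0 * (2.0 / 3.5) ** 3
        assert buried_volume(s, [0], spec) == pytest.approx(expected, abs=0.5)

    def test_two_atom_overlap_vs_monte_carlo_oracle(self, rng):
        s = _structure(["C", "O"], [[0.4, 0.2, -0.3], [1.6, -0.5, 0.8]])
        spec = BuriedVolumeSpec(center=np.zeros(3), sphere_radius=3.5)
        got = buried_volume(s, [0, 1], spec)
        # independent oracle: rejection sampling, 1e6 points uniform in sphere
        n = 1_000_000
        pts = rng.uniform(-3.5, 3.5, size=(2 * n, 3))
        pts = pts[np.einsum("ij,ij->i", pts, pts) <= 3.5**2][:n]
        radii = np.array([VDW_RADII["C"], VDW_RADII["O"]]) * spec.radii_scale
        inside = np.zeros(len(pts), dtype=bool)
        for pos, r in zip(s.coords, radii):
            inside |= np.einsum("ij,ij->i", pts - pos, pts - pos) <= r**2
        oracle = 100.0 * inside.mean()
        assert got == pytest.approx(oracle, abs=0.5)

    def test_monotone_under_added_atoms_and_bounded(self, rng):
        coords = rng.uniform(-2.5, 2.5, size=(6, 3))
        s = _structure(["C"] * 6, coords)
        spec = BuriedVolumeSpec(center=np.zeros(3))
        values = [buried_volume(s, list(range(k)), spec) for k in range(7)]
        assert values[0] == 0.0
        for a, b in zip(values, values[1:]):
            assert b >= a - 1e-12
        assert all(0.0 <= v <= 100.0 for v in values)

    def test_rigid_rotation_invariance(self, rng):
        coords = rng.uniform(-2.5, 2.5, size=(5, 3))
        s = _structure(["C"] * 5, coords)
        spec = BuriedVolumeSpec(center=np.zeros(3))
        base = buried_volume(s, range(5), spec)
        R = _rotation(rng)
        s_rot = _structure(["C"] * 5, coords @ R.T)
        assert buried_volume(s_rot, range(5), spec) == pytest.approx(base, abs=0.3)


class TestQuadrantBuriedVolume:
    Z = np.array([0.0, 0.0, 1.0])
    X = np.array([1.0, 0.0, 0.0])

    def test_single_atom_on_x_axis_splits_between_x_positive_quadrants(self):
        # far enough out that the whole atom sphere stays at x > 0
        s = _structure(["C"], [[2.5, 0.0, 0.0]])
        spec = BuriedVolumeSpec(center=np.zeros(3))
        q = quadrant_buried_volume(s, [0], spec, self.Z, self.X)
        assert q["Q2"] == 0.0 and q["Q3"] == 0.0
        assert q["Q1"] > 0 and q["Q1"] == pytest.approx(q["Q4"], abs=0.5)

    def test_quadrant_mean_equals_total(self, rng):
        coords = rng.uniform(-2.5, 2.5, size=(6, 3))
        s = _structure(["C"] * 6, coords)
        spec = BuriedVolumeSpec(center=np.zeros(3))
        q = quadrant_buried_volume(s, range(6), spec, self.Z, self.X)
        total = buried_volume(s, range(6), spec)
        assert np.mean(list(q.values())) == pytest.approx(total, abs=0.2)

    def test_c2_symmetric_fixture_pairs_equal(self):
        # two-fold rotation about the frame z-axis maps Q1<->Q3 and Q2<->Q4
        coords = [[1.2, 0.8, 0.5], [-1.2, -0.8, 0.5], [0.5, -1.4, -0.7], [-0.5, 1.4, -0.7]]
        s = _structure(["C"] * 4, coords)
        spec = BuriedVolumeSpec(center=np.zeros(3))
        q = quadrant_buried_volume(s, range(4), spec, self.Z, self.X)
        assert q["Q1"] == pytest.approx(q["Q3"], abs=0.5)
        assert q["Q2"] == pytest.approx(q["Q4"], abs=0.5)

    def test_degenerate_frame_raises(self):
        s = _structure(["C"], [[1.0, 0, 0]])
        spec = BuriedVolumeSpec(center=np.zeros(3))
        with pytest.raises(ValueError, match="degenerate"):
            quadrant_buried_volume(s, [0], spec, self.Z, self.Z)


class TestExactConeAngle:
    def test_single_atom_closed_form(self):
        s = _structure(["Rh", "P"], [[0, 0, 0], [2.28, 0, 0]])
        res = exact_cone_angle(s, apex=0, atom_subset=[1])
        expected = 2.0 * math.degrees(math.asin(VDW_RADII["P"] / 2.28))
        assert res.angle == pytest.approx(expected, abs=0.1)

    def test_two_atoms_vs_brute_force_axis_grid(self):
        s = _structure(
            ["Rh", "P", "P"], [[0, 0, 0], [1.6, 1.7, 0.2], [1.6, -1.7, -0.2]]
        )
        res = exact_cone_angle(s, apex=0, atom_subset=[1, 2])
        # independent oracle: exhaustive scan over 1e6 Fibonacci directions
        n = 1_000_000
        k = np.arange(n)
        phi = math.pi * (3.0 - math.sqrt(5.0)) * k
        z = 1.0 - 2.0 * (k + 0.5) / n
        r = np.sqrt(1.0 - z**2)
        axes = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        rel = s.coords[1:] - s.coords[0]
        d = np.linalg.norm(rel, axis=1)
        units = rel / d[:, None]
        beta = np.arcsin(VDW_RADII["P"] / d)
        half = np.arccos(np.clip(axes @ units.T, -1, 1)) + beta[None, :]
        oracle = 2.0 * math.degrees(half.max(axis=1).min())
        assert res.angle == pytest.approx(oracle, abs=0.1)
        assert res.angle <= oracle + 1e-6  # optimizer at least matches the scan

    def test_atom_inside_cone_changes_nothing(self):
        s = _structure(
            ["Rh", "P", "P", "H"],
            [[0, 0, 0], [1.6, 1.7, 0], [1.6, -1.7, 0], [2.4, 0, 0]],
        )
        two = exact_cone_angle(s, apex=0, atom_subset=[1, 2])
        three = exact_cone_angle(s, apex=0, atom_subset=[1, 2, 3])
        assert three.angle == pytest.approx(two.angle, abs=1e-3)

    def test_never_decreases_when_atoms_added(self, rng):
        coords = np.vstack([[0, 0, 0], rng.uniform(2.5, 5.0, size=(4, 3))])
        s = _structure(["Rh"] + ["C"] * 4, coords)
        angles = [
            exact_cone_angle(s, 0, list(range(1, 1 + k))).angle for k in range(1, 5)
        ]
        for a, b in zip(angles, angles[1:]):
            assert b >= a - 1e-6

    def test_rotation_invariance(self, rng):
        coords = np.vstack([[0, 0, 0], rng.uniform(2.5, 5.0, size=(3, 3))])
        s = _structure(["Rh", "C", "C", "C"], coords)
        base = exact_cone_angle(s, 0, [1, 2, 3]).angle
        R = _rotation(rng)
        s_rot = _structure(["Rh", "C", "C", "C"], coords @ R.T)
        assert exact_cone_angle(s_rot, 0, [1, 2, 3]).angle == pytest.approx(base, abs=1e-3)

    def test_engulfing_sphere_raises(self):
        s = _structure(["Rh", "P"], [[0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError, match="cone undefined"):
            exact_cone_angle(s, 0, [1])


class TestSterimol:
    def test_single_hydrogen_closed_form(self):
        s = _structure(["C", "H"], [[0, 0, 0], [1.09, 0, 0]])
        res = sterimol(s, attach=0, first=1, atom_subset=[1])
        assert res.L == pytest.approx(1.09 + STERIMOL_RADII["H"], abs=1e-9)
        assert res.B1 == pytest.approx(STERIMOL_RADII["H"], abs=1e-6)
        assert res.B5 == pytest.approx(STERIMOL_RADII["H"], abs=1e-9)

    def test_three_atom_fixture_vs_brute_force(self):
        s = _structure(
            ["C", "C", "Cl", "H"],
            [[0, 0, 0], [1.5, 0, 0], [2.2, 1.5, 0.4], [2.1, -0.8, -0.9]],
        )
        subset = [1, 2, 3]
        res = sterimol(s, attach=0, first=1, atom_subset=subset)
        # independent oracle: direct formulas + 36 000-direction B1 scan
        u = np.array([1.0, 0.0, 0.0])
        rel = s.coords[subset]
        rads = np.array([STERIMOL_RADII[s.elements[i]] for i in subset])
        proj = rel @ u
        perp_vec = rel - np.outer(proj, u)
        L = np.max(proj + rads)
        B5 = np.max(np.linalg.norm(perp_vec, axis=1) + rads)
        th = np.deg2rad(np.arange(0, 360, 0.01))
        dirs = np.stack([np.zeros_like(th), np.cos(th), np.sin(th)], axis=1)
        B1 = np.min((perp_vec @ dirs.T + rads[:, None]).max(axis=0))
        assert res.L == pytest.approx(L, abs=0.01)
        assert res.B5 == pytest.approx(B5, abs=0.01)
        assert res.B1 == pytest.approx(B1, abs=0.01)

    def test_b1_never_exceeds_b5(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 7))
            coords = np.vstack([[0, 0, 0], [1.4, 0, 0], rng.uniform(-3, 3, size=(n, 3)) + [2, 0, 0]])
            s = _structure(["C"] * (n + 2), coords)
            res = sterimol(s, 0, 1, list(range(1, n + 2)))
            assert res.B1 <= res.B5 + 1e-9
            assert res.L > 0

    def test_zero_axis_raises(self):
        s = _structure(["C", "C"], [[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="zero-length"):
            sterimol(s, 0, 1, [1])


class TestAnglesAndDistances:
    def test_orthogonal_donors(self):
        s = _structure(["Rh", "P", "P"], [[0, 0, 0], [2, 0, 0], [0, 2, 0]])
        assert bite_angle(s, 0, 1, 2) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_is_180(self):
        s = _structure(["Rh", "P", "P"], [[0, 0, 0], [2, 0, 0], [-2, 0, 0]])
        assert bite_angle(s, 0, 1, 2) == pytest.approx(180.0, abs=1e-9)

    def test_law_of_cosines_oracle(self, rng):
        coords = rng.uniform(-3, 3, size=(3, 3))
        s = _structure(["Rh", "P", "P"], coords)
        a = np.linalg.norm(coords[1] - coords[0])
        b = np.linalg.norm(coords[2] - coords[0])
        c = np.linalg.norm(coords[2] - coords[1])
        expected = math.degrees(math.acos((a**2 + b**2 - c**2) / (2 * a * b)))
        assert bite_angle(s, 0, 1, 2) == pytest.approx(expected, abs=1e-9)

    def test_coplanar_dihedral_is_0_or_180(self):
        assert abs(dihedral_4pt([0, 1, 0], [0, 0, 0], [1, 0, 0], [2, 1, 0])) \
            == pytest.approx(0.0, abs=1e-9)
        assert abs(dihedral_4pt([0, 1, 0], [0, 0, 0], [1, 0, 0], [2, -1, 0])) \
            == pytest.approx(180.0, abs=1e-9)

    def test_mirror_negates_dihedral(self, rng):
        pts = rng.uniform(-2, 2, size=(4, 3))
        d = dihedral_4pt(*pts)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral_4pt(*mirrored) == pytest.approx(-d, abs=1e-9)

    def test_dihedral_vs_independent_vector_algebra(self, rng):
        p0, p1, p2, p3 = rng.uniform(-2, 2, size=(4, 3))
        # oracle: angle between plane normals, signed by a triple product
        n1 = np.cross(p1 - p0, p2 - p1)
        n2 = np.cross(p2 - p1, p3 - p2)
        cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
        ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
        if np.dot(np.cross(n1, n2), p2 - p1) > 0:
            ang = -ang
        assert dihedral_4pt(p0, p1, p2, p3) == pytest.approx(ang, abs=1e-6)

    def test_distance_and_centroid(self, rng):
        s = _structure(["C", "C"], [[0, 0, 0], [3, 4, 0]])
        assert distance(s, 0, 1) == 5.0
        np.testing.assert_allclose(centroid(s, [0, 1]), [1.5, 2.0, 0.0])
        coords = rng.uniform(-5, 5, size=(4, 3))
        s2 = _structure(["C"] * 4, coords)
        assert distance(s2, 1, 3) == pytest.approx(np.linalg.norm(coords[1] - coords[3]))
        np.testing.assert_allclose(centroid(s2, range(4)), coords.mean(axis=0))
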