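"""Structure operations: PDB IO, Kabsch, extents, tiling, pseudo-AFM."""

import math

import numpy as np
import pytest

from crystafm import structure as struct
from crystafm.core import Lattice2D, Topograph

from conftest import toy_structure

PDB_MINIMAL = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   2.500   3.500  1.00  0.00           C
ATOM      3  C   ALA A   1       3.000   2.000   4.000  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.70  0.00           C
END
"""


class TestReadStructure:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(PDB_MINIMAL)
        s = struct.read_structure(p)
        assert len(s) == 3
        np.testing.assert_allclose(s.coord[0], [1.0, 2.0, 3.0])
        assert list(s.atom_name) == ["N", "CA", "C"]

    def test_altloc_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        s = struct.read_structure(p)
        assert len(s) == 1
        assert s.coord[0, 0] == pytest.approx(9.0)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError):
            struct.read_structure(p)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestKabsch:
    def test_self_rmsd_zero(self):
        rng = np.random.default_rng(0)
        s = toy_structure(rng.normal(size=(20, 3)) * 5)
        rmsd, R, t = struct.kabsch_rmsd(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(30, 3)) * 8
        Rtrue = random_rotation(rng)
        moved = coords @ Rtrue.T + np.array([5.0, -3.0, 11.0])
        ref = toy_structure(coords)
        mob = toy_structure(moved)
        rmsd, R, t = struct.kabsch_rmsd(ref, mob)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(mob.coord @ R.T + t, coords, atol=1e-9)

    def test_matches_quaternion_grid_brute_force(self):
        # independent oracle: dense random-quaternion search on a 8-atom toy
        rng = np.random.default_rng(2)
        P = rng.normal(size=(8, 3)) * 3
        Q = P @ random_rotation(rng).T + rng.normal(size=(8, 3)) * 0.3
        ref, mob = toy_structure(P), toy_structure(Q)
        rmsd, _, _ = struct.kabsch_rmsd(ref, mob)
        P0 = P - P.mean(axis=0)
        Q0 = Q - Q.mean(axis=0)

        def cost(q):
            q = q / np.linalg.norm(q)
            w, x, y, z = q
            R = np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
                ]
            )
            return np.sqrt(np.mean(np.sum((Q0 @ R.T - P0) ** 2, axis=1)))

        rng2 = np.random.default_rng(3)
        best_q, best = None, np.inf
        for _ in range(20_000):
            q = rng2.normal(size=4)
            val = cost(q)
            if val < best:
                best, best_q = val, q / np.linalg.norm(q)
        # local refinement: shrinking random perturbations of the quaternion
        scale = 0.1
        while scale > 1e-6:
            improved = False
            for _ in range(200):
                q = best_q + scale * rng2.normal(size=4)
                val = cost(q)
                if val < best:
                    best, best_q = val, q / np.linalg.norm(q)
                    improved = True
            if not improved:
                scale /= 3.0
        assert rmsd <= best + 1e-9
        assert best - rmsd < 1e-3

    def test_correspondence_failure_reported(self):
        ref = toy_structure(np.zeros((3, 3)), res_ids=[1, 2, 3])
        mob = toy_structure(np.zeros((3, 3)), res_ids=[1, 2, 4])
        with pytest.raises(ValueError, match="unmatched"):
            struct.kabsch_rmsd(ref, mob)


class TestVerticalExtent:
    def test_rod_extent(self):
        coords = np.zeros((11, 3))
        coords[:, 2] = np.linspace(0, 50, 11)
        s = toy_structure(coords)
        assert struct.vertical_extent(s, axis=(0, 0, 1)) == pytest.approx(5.0)

    def test_principal_axis_default(self):
        coords = np.zeros((11, 3))
        coords[:, 2] = np.linspace(0, 50, 11)
        coords[:, 0] = np.linspace(0, 3, 11)
        s = toy_structure(coords)
        assert struct.vertical_extent(s) == pytest.approx(
            np.hypot(50, 3) / 10, abs=0.01)

    def test_terminal_exclusion_shortens(self):
        coords = np.zeros((10, 3))
        coords[:, 2] = np.arange(10) * 5.0
        s = toy_structure(coords)
        full = struct.vertical_extent(s, axis=(0, 0, 1))
        trimmed = struct.vertical_extent(s, axis=(0, 0, 1),
                                         exclude_n_term=1, exclude_c_term=2)
        assert full == pytest.approx(4.5)
        assert trimmed == pytest.approx(3.0)

    def test_all_excluded_rejected(self):
        s = toy_structure(np.zeros((2, 3)), res_ids=[1, 2])
        with pytest.raises(ValueError):
            struct.vertical_extent(s, exclude_n_term=1, exclude_c_term=1)


class TestTileCrystal:
    @pytest.fixture
    def unit(self):
        rng = np.random.default_rng(5)
        return toy_structure(rng.normal(size=(7, 3)) * 4)

    def test_identity_copy(self, unit):
        lat = Lattice2D(10.8, 6.6, 100.0)
        tiled = struct.tile_crystal(unit, lat, 1, 1)
        np.testing.assert_allclose(tiled.coord, unit.coord)
        assert len(tiled) == len(unit)

    def test_4_by_7_array(self, unit):
        lat = Lattice2D(10.8, 6.6, 100.0)
        tiled = struct.tile_crystal(unit, lat, 4, 7)
        assert len(tiled) == 28 * len(unit)
        assert len(set(tiled.chain_id)) == 28

    def test_adjacent_copies_differ_by_a(self, unit):
        lat = Lattice2D(10.8, 6.6, 100.0, orientation=30.0)
        tiled = struct.tile_crystal(unit, lat, 2, 1)
        n = len(unit)
        delta = tiled.coord[n:] - tiled.coord[:n]
        expected = np.append(lat.a_vec * 10.0, 0.0)
        np.testing.assert_allclose(delta, np.tile(expected, (n, 1)), atol=1e-9)


class TestPseudoAfm:
    def test_flat_surface_unchanged(self):
        topo = Topograph(np.full((32, 32), 4.0), 0.25)
        tip = struct.TipModel(radius=0.5, half_angle=8.0, scan_step=0.25)
        out = struct.pseudo_afm(topo, tip)
        np.testing.assert_allclose(out.heights, 4.0)

    def test_point_tip_is_identity(self):
        rng = np.random.default_rng(6)
        topo = Topograph(rng.uniform(0, 3, (24, 24)), 0.25)
        tip = struct.TipModel(radius=0.0, half_angle=1e-4, scan_step=0.25)
        out = struct.pseudo_afm(topo, tip)
        np.testing.assert_allclose(out.heights, topo.heights)

    def test_spike_dilates_to_spherical_cap(self):
        h = 5.0
        step = 0.05
        n = 81
        img = np.zeros((n, n))
        img[n // 2, n // 2] = h
        tip = struct.TipModel(radius=0.5, half_angle=8.0, scan_step=step)
        out = struct.pseudo_afm(Topograph(img, step), tip).heights
        R = tip.radius
        r_t = R * math.cos(math.radians(tip.half_angle))
        for dx_px in range(0, int(r_t / step)):
            r = dx_px * step
            expected = h - R + math.sqrt(R**2 - r**2)
            assert out[n // 2, n // 2 + dx_px] == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_dilation(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 4, (64, 64))
        step = 0.25
        tip = struct.TipModel(radius=0.8, half_angle=15.0, scan_step=step)
        out = struct.pseudo_afm(Topograph(img, step), tip).heights
        # exhaustive max-search oracle over the tip support
        k = int(tip.support_radius(img.max() - img.min()) / step)
        n = img.shape[0]
        oracle = np.empty_like(img)
        for i in range(n):
            for j in range(n):
                best = -np.inf
                for di in range(-k, k + 1):
                    ii = min(max(i + di, 0), n - 1)
                    for dj in range(-k, k + 1):
                        jj = min(max(j + dj, 0), n - 1)
                        r = math.hypot(di, dj) * step
                        best = max(best, img[ii, jj] - tip.height(np.array(r)))
                oracle[i, j] = best
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_dilation_extensive_and_monotone(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 3, (32, 32))
        b = a + rng.uniform(0, 1, (32, 32))
        tip = struct.TipModel(radius=1.0, half_angle=10.0, scan_step=0.25)
        da = struct.pseudo_afm(Topograph(a, 0.25), tip).heights
        db = struct.pseudo_afm(Topograph(b, 0.25), tip).heights
        assert np.all(da >= a - 1e-12)
        assert np.all(db >= da - 1e-12)

    def test_atomic_envelope_height(self):
        # single C atom (vdW 1.7 A): envelope top = 2 r_vdw above base plane
        s = toy_structure([[0.0, 0.0, 5.0]], elements=["C"])
        tip = struct.TipModel(radius=0.0, half_angle=1e-4, scan_step=0.05)
        out = struct.pseudo_afm(s, tip)
        assert out.heights.max() == pytest.approx(0.34, abs=1e-6)


class TestDepthContours:
    def hemisphere(self, R=3.0, step=0.05):
        n = int(2 * R / step) + 21
        yy, xx = np.mgrid[0:n, 0:n]
        x = (xx - n // 2) * step
        y = (yy - n // 2) * step
        r2 = x**2 + y**2
        h = np.where(r2 <= R**2, np.sqrt(np.maximum(R**2 - r2, 0.0)), 0.0)
        return Topograph(h, step)

    def test_hemisphere_contour_radius(self):
        topo = self.hemisphere(R=3.0)
        cs = struct.depth_contours(topo, [1.0])
        (polys,) = cs.polylines
        assert len(polys) >= 1
        poly = max(polys, key=len)
        center = poly.mean(axis=0)
        radii = np.linalg.norm(poly - center, axis=1)
        assert radii.mean() == pytest.approx(math.sqrt(5.0), abs=0.05)

    def test_nested_levels_nested_contours(self):
        topo = self.hemisphere(R=3.0)
        cs = struct.depth_contours(topo, [0.5, 1.0, 2.0])
        radii = []
        for polys in cs.polylines:
            poly = max(polys, key=len)
            c = poly.mean(axis=0)
            radii.append(np.linalg.norm(poly - c, axis=1).mean())
        assert radii[0] < radii[1] < radii[2]

    def test_level_below_minimum_flagged(self):
        topo = self.hemisphere(R=3.0)
        with pytest.warns(UserWarning, match="minimum"):
            cs = struct.depth_contours(topo, [5.0])
        assert cs.empty_levels == [5.0]
        assert cs.polylines == [[]]

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            struct.depth_contours(Topograph(np.ones((8, 8)), 0.5), [1.0])
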