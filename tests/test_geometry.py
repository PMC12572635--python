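import itertools
import math

import numpy as np
import pytest

from znsite import fixtures, geometry
from znsite.errors import ContractViolationError, DegenerateGeometryError
from znsite.fixtures import SiteSpec, build_residue, make_ideal_site
from znsite.geometry import (
    ChosenAtom,
    choose_three_residue_side,
    imidazole_angles,
    initial_zinc_estimate,
    refine_zinc_position,
    rotate_his_chi2,
    sample_his_rotamers,
    select_binding_atoms,
    site_his_angles,
    site_his_angles_score,
    superimpose_rmsd,
)
from znsite.structure_model import Atom, Residue, binding_point

TETRA = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3)


def _cys_at(coord, chain="A", seq=1):
    return Residue(chain, seq, "CYS", [Atom("SG", "S", coord)])


def _ser_at(coord, chain="A", seq=1):
    return Residue(chain, seq, "SER", [Atom("OG", "O", coord)])


# ---------------------------------------------------------------------------
# initial estimate
# ---------------------------------------------------------------------------

class TestInitialEstimate:
    def test_tetrahedron_centroid(self):
        residues = [_cys_at(2.15 * u, seq=i + 1) for i, u in enumerate(TETRA)]
        starts = initial_zinc_estimate(residues)
        assert len(starts) == 1
        np.testing.assert_allclose(starts[0], [0, 0, 0], atol=1e-12)

    def test_triangle_two_sides(self):
        pts = [(1, 0, 0), (-0.5, math.sqrt(3) / 2, 0), (-0.5, -math.sqrt(3) / 2, 0)]
        residues = [_ser_at(np.array(p) * 2, seq=i + 1) for i, p in enumerate(pts)]
        starts = initial_zinc_estimate(residues)
        assert len(starts) == 2
        zs = sorted(s[2] for s in starts)
        assert zs == pytest.approx([-1.5, 1.5], abs=1e-9)
        np.testing.assert_allclose([s[:2] for s in starts], 0, atol=1e-9)

    def test_collinear_raises(self):
        residues = [_ser_at((float(i), 0, 0), seq=i + 1) for i in range(3)]
        with pytest.raises(DegenerateGeometryError):
            initial_zinc_estimate(residues)

    def test_too_few_residues(self):
        with pytest.raises(ContractViolationError):
            initial_zinc_estimate([_cys_at((0, 0, 0))])


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------

class TestSelectBindingAtoms:
    def test_nearest_nitrogen(self):
        his = Residue("A", 1, "HIS", [
            Atom("ND1", "N", (2.1, 0, 0)), Atom("NE2", "N", (4.0, 0, 0)),
        ])
        [chosen] = select_binding_atoms([his, _cys_at((0, 9, 0), seq=2),
                                         _cys_at((0, 0, 9), seq=3)],
                                        np.zeros(3))[:1]
        assert chosen.atom_name == "ND1"

    def test_tie_breaks_lexicographically(self):
        his = Residue("A", 1, "HIS", [
            Atom("NE2", "N", (2.0, 0, 0)), Atom("ND1", "N", (-2.0, 0, 0)),
        ])
        chosen = select_binding_atoms([his], np.zeros(3))
        assert chosen[0].atom_name == "ND1"

    def test_glu_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            oe1, oe2 = rng.normal(0, 3, 3), rng.normal(0, 3, 3)
            est = rng.normal(0, 3, 3)
            glu = Residue("A", 1, "GLU", [Atom("OE1", "O", oe1), Atom("OE2", "O", oe2)])
            [chosen] = select_binding_atoms([glu], est)
            brute = min(
                [("OE1", oe1), ("OE2", oe2)],
                key=lambda nc: (np.linalg.norm(nc[1] - est), nc[0]),
            )
            assert chosen.atom_name == brute[0]

    def test_single_atom_residue(self):
        cys = _cys_at((1, 2, 3))
        chosen = select_binding_atoms([cys], np.zeros(3))
        assert chosen[0].atom_name == "SG"
        assert chosen[0].d_ideal == 2.32


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def _objective(point, chosen):
    return sum(
        (np.linalg.norm(c.coord - point) - c.d_ideal) ** 2 for c in chosen
    )


def grid_scan(coords, ideals, center, half, step):
    """Brute-force grid minimizer of the placement objective (oracle)."""
    g = np.arange(-half, half + step / 2, step)
    best_val, best_pt = np.inf, None
    for zx in g:
        pts = np.array(np.meshgrid([zx], g, g)).reshape(3, -1).T + center
        d = np.linalg.norm(pts[:, None, :] - coords[None], axis=2)
        o = ((d - ideals) ** 2).sum(axis=1)
        i = o.argmin()
        if o[i] < best_val:
            best_val, best_pt = o[i], pts[i]
    return best_val, best_pt


class TestRefine:
    def test_regular_tetrahedron_exact(self):
        residues = [_ser_at(2.15 * u, seq=i + 1) for i, u in enumerate(TETRA)]
        chosen = select_binding_atoms(residues, np.array([0.05, -0.02, 0.01]))
        res = refine_zinc_position(chosen, np.array([0.05, -0.02, 0.01]))
        np.testing.assert_allclose(res.zinc_coord, 0, atol=1e-4)
        assert res.drmsd < 1e-6
        assert res.converged

    def test_triangle_apex_closed_form(self):
        side = 3.3
        r = side / math.sqrt(3)
        h = math.sqrt(2.15**2 - r**2)  # ~0.9962
        pts = [
            (r, 0, 0),
            (-r / 2, r * math.sqrt(3) / 2, 0),
            (-r / 2, -r * math.sqrt(3) / 2, 0),
        ]
        residues = [_ser_at(p, seq=i + 1) for i, p in enumerate(pts)]
        chosen = select_binding_atoms(residues, np.array([0, 0, 1.5]))
        res = refine_zinc_position(chosen, np.array([0, 0, 1.5]))
        assert res.zinc_coord[2] == pytest.approx(h, abs=1e-3)
        assert abs(h - 0.997) < 1e-3
        assert res.drmsd < 1e-6

    def test_matches_grid_oracle_on_random_sites(self):
        # perturbed-tetrahedron sites; two-stage (coarse then fine) grid oracle
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            dirs = TETRA + rng.normal(0, 0.25, TETRA.shape)
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            radii = rng.uniform(1.9, 2.6, 4)
            residues = [
                _ser_at(d * r, seq=i + 1) for i, (d, r) in enumerate(zip(dirs, radii))
            ]
            start = initial_zinc_estimate(residues)[0]
            chosen = select_binding_atoms(residues, start)
            res = refine_zinc_position(chosen, start)
            coords = np.array([c.coord for c in chosen])
            ideals = np.array([c.d_ideal for c in chosen])
            _, coarse = grid_scan(coords, ideals, coords.mean(axis=0), 2.5, 0.05)
            fine_val, fine_pt = grid_scan(coords, ideals, coarse, 0.1, 0.01)
            assert np.linalg.norm(res.zinc_coord - fine_pt) <= 0.01 * math.sqrt(3)
            assert _objective(res.zinc_coord, chosen) <= fine_val + 1e-9

    def test_objective_not_worse_than_start(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            residues = [
                _ser_at(rng.normal(0, 2, 3), seq=i + 1) for i in range(4)
            ]
            start = rng.normal(0, 1, 3)
            chosen = select_binding_atoms(residues, start)
            res = refine_zinc_position(chosen, start)
            assert _objective(res.zinc_coord, chosen) <= _objective(start, chosen) + 1e-12

    def test_drmsd_rotation_invariant(self):
        from scipy.spatial.transform import Rotation

        spec = SiteSpec(("HIS", "HIS", "GLU", "CYS"), "tetrahedral")
        s1 = make_ideal_site(spec, zinc_coord=(0, 0, 0))
        s1 = fixtures.perturb_site(s1, 0.15, seed=4)
        rot = Rotation.from_euler("xyz", [31, -77, 12], degrees=True).as_matrix()
        s2 = fixtures.transform_structure(s1, rot, np.array([5.0, -3.0, 2.0]))

        def run(structure):
            residues = structure.residues
            start = initial_zinc_estimate(residues)[0]
            chosen = select_binding_atoms(residues, start)
            return refine_zinc_position(chosen, start).drmsd

        assert run(s1) == pytest.approx(run(s2), abs=1e-6)

    def test_mirror_placements_equal_drmsd(self):
        spec = SiteSpec(("ASP", "GLU", "SER"), "trigonal_apex")
        s = make_ideal_site(spec, zinc_coord=(0, 0, 0))
        s = fixtures.perturb_site(s, 0.1, seed=9)
        starts = initial_zinc_estimate(s.residues)
        results = []
        for start in starts:
            chosen = select_binding_atoms(s.residues, start)
            results.append(refine_zinc_position(chosen, start))
        assert results[0].drmsd == pytest.approx(results[1].drmsd, abs=1e-6)


# ---------------------------------------------------------------------------
# imidazole angles
# ---------------------------------------------------------------------------

class TestImidazoleAngles:
    def setup_method(self):
        self.zinc = np.zeros(3)
        self.his = build_residue("HIS", self.zinc, (0, 0, 1), 2.15)

    def test_ideal_geometry_zero_angles(self):
        ang = imidazole_angles(self.his, self.zinc, "NE2")
        assert ang.alpha == pytest.approx(0.0, abs=1e-6)
        assert ang.beta == pytest.approx(0.0, abs=1e-6)

    def test_zinc_along_normal_alpha_90(self):
        ring = np.array(
            [self.his.require_atom(n).coord for n in ("CG", "ND1", "CD2", "CE1", "NE2")]
        )
        centered = ring - ring.mean(axis=0)
        normal = np.linalg.svd(centered)[2][2]
        n_coord = self.his.require_atom("NE2").coord
        ang = imidazole_angles(self.his, n_coord + 2.15 * normal, "NE2")
        assert ang.alpha == pytest.approx(90.0, abs=1e-4)

    def test_constructed_20_degree_elevation(self):
        n_coord = self.his.require_atom("NE2").coord
        c1 = self.his.require_atom("CD2").coord
        c2 = self.his.require_atom("CE1").coord
        m = 0.5 * (c1 + c2)
        in_plane = (n_coord - m) / np.linalg.norm(n_coord - m)
        ring = np.array(
            [self.his.require_atom(n).coord for n in ("CG", "ND1", "CD2", "CE1", "NE2")]
        )
        normal = np.linalg.svd(ring - ring.mean(axis=0))[2][2]
        elev = math.radians(20.0)
        direction = math.cos(elev) * in_plane + math.sin(elev) * normal
        ang = imidazole_angles(self.his, n_coord + 2.15 * direction, "NE2")
        assert ang.alpha == pytest.approx(20.0, abs=1e-6)
        assert ang.beta == pytest.approx(0.0, abs=1e-4)

    def test_independent_recomputation_oracle(self):
        # independent reimplementation from three explicit ring atoms
        his = rotate_his_chi2(self.his, 37.0)
        zinc = np.array([0.3, -0.4, 0.2])
        ang = imidazole_angles(his, zinc, "NE2")
        cg = his.require_atom("CG").coord
        nd1 = his.require_atom("ND1").coord
        ne2 = his.require_atom("NE2").coord
        cd2 = his.require_atom("CD2").coord
        ce1 = his.require_atom("CE1").coord
        n = np.cross(nd1 - cg, cd2 - cg)
        n /= np.linalg.norm(n)
        bond = zinc - ne2
        alpha = abs(90.0 - math.degrees(
            math.acos(np.clip(np.dot(bond / np.linalg.norm(bond), n), -1, 1))
        ))
        m = 0.5 * (cd2 + ce1)
        mn = ne2 - m
        proj = bond - np.dot(bond, n) * n
        beta = math.degrees(
            math.acos(np.clip(
                np.dot(proj / np.linalg.norm(proj), mn / np.linalg.norm(mn)), -1, 1
            ))
        )
        assert ang.alpha == pytest.approx(alpha, abs=1e-6)
        assert ang.beta == pytest.approx(beta, abs=1e-6)

    def test_missing_ring_atom(self):
        broken = Residue("A", 1, "HIS", [
            a for a in self.his.atoms if a.name != "CE1"
        ])
        from znsite.errors import MissingAtomError

        with pytest.raises(MissingAtomError):
            imidazole_angles(broken, self.zinc, "NE2")

    def test_angle_ranges(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            zinc = self.his.require_atom("NE2").coord + rng.normal(0, 2, 3)
            ang = imidazole_angles(self.his, zinc, "NE2")
            assert 0 <= ang.alpha <= 90
            assert 0 <= ang.beta <= 180


# ---------------------------------------------------------------------------
# side selection
# ---------------------------------------------------------------------------

class TestSideSelection:
    def _placements(self, structure):
        starts = initial_zinc_estimate(structure.residues)
        results, scores = [], []
        for start, label in zip(starts, ["A", "B"]):
            chosen = select_binding_atoms(structure.residues, start)
            res = refine_zinc_position(chosen, start, side_label=label)
            results.append(res)
            scores.append(site_his_angles_score(chosen, res.zinc_coord))
        return results, scores

    def test_his_picks_construction_side(self):
        s = make_ideal_site(SiteSpec(("HIS", "HIS", "HIS"), "trigonal_apex"),
                            zinc_coord=(0, 0, 0))
        results, scores = self._placements(s)
        [picked] = choose_three_residue_side(results, scores)
        np.testing.assert_allclose(picked.zinc_coord, 0, atol=1e-4)

    def test_no_his_always_side_a(self):
        s = make_ideal_site(SiteSpec(("ASP", "GLU", "SER"), "trigonal_apex"),
                            zinc_coord=(0, 0, 0))
        for _ in range(3):
            results, scores = self._placements(s)
            [picked] = choose_three_residue_side(results, scores)
            assert picked.side_label == "A"

    def test_tie_goes_to_side_a(self):
        res_a = object.__new__(geometry.PlacementResult)
        results, scores = [1, 2], [5.0, 5.0]
        picked = choose_three_residue_side(results, scores)
        assert picked == [1]

    def test_both_sides_flag(self):
        picked = choose_three_residue_side([1, 2], [5.0, 1.0], both_sides=True)
        assert picked == [1, 2]


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _oracle_kabsch(P, Q):
    """Independent Kabsch: optimal RMSD superimposing P onto Q."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ P.T).T - Q
    return math.sqrt((diff**2).sum() / len(P))


class TestSuperimposeRmsd:
    def test_exact_copy_zero(self):
        atoms = [("HIS", np.array([0, 0, 0.0])), ("HIS", np.array([3, 0, 0.0])),
                 ("GLU", np.array([0, 3, 0.0]))]
        assert superimpose_rmsd(atoms, atoms) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        coords = rng.normal(0, 3, (4, 3))
        atoms = [("HIS", c) for c in coords[:2]] + [("CYS", c) for c in coords[2:]]
        rot = Rotation.from_euler("zyx", [10, 50, -30], degrees=True).as_matrix()
        moved = [(t, rot @ c + np.array([1, 2, 3])) for t, c in atoms]
        assert superimpose_rmsd(atoms, moved) == pytest.approx(0.0, abs=1e-6)

    def test_displaced_atom_matches_oracle(self):
        base = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0.0]])
        moved = base.copy()
        moved[0] += [0.0, 0.0, 0.3]
        site = [("HIS", c) for c in base]
        tmpl = [("HIS", c) for c in moved]
        got = superimpose_rmsd(site, tmpl)
        brute = min(
            _oracle_kabsch(moved[list(p)], base) for p in itertools.permutations(range(3))
        )
        assert got == pytest.approx(brute, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a = [("HIS", rng.normal(0, 2, 3)) for _ in range(2)] + [("CYS", rng.normal(0, 2, 3))]
        b = [("HIS", rng.normal(0, 2, 3)) for _ in range(2)] + [("CYS", rng.normal(0, 2, 3))]
        assert superimpose_rmsd(a, b) == pytest.approx(superimpose_rmsd(b, a), abs=1e-9)

    def test_multiset_mismatch(self):
        a = [("HIS", np.zeros(3)), ("HIS", np.ones(3)), ("GLU", 2 * np.ones(3))]
        b = [("HIS", np.zeros(3)), ("CYS", np.ones(3)), ("GLU", 2 * np.ones(3))]
        with pytest.raises(ContractViolationError):
            superimpose_rmsd(a, b)

    def test_permutation_enumeration_beats_fixed_pairing(self):
        # swapped same-type atoms must still superimpose to ~0
        base = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0.0]])
        site = [("HIS", base[0]), ("HIS", base[1]), ("GLU", base[2])]
        tmpl = [("HIS", base[1]), ("HIS", base[0]), ("GLU", base[2])]
        assert superimpose_rmsd(site, tmpl) == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# rotamer sampling
# ---------------------------------------------------------------------------

class TestRotamerSampling:
    def test_chi2_rotation_geometry(self):
        his = build_residue("HIS", np.zeros(3), (0, 0, 1), 2.15)
        rotated = rotate_his_chi2(his, 25.0)
        for fixed in ("CA", "CB", "CG"):
            np.testing.assert_allclose(
                his.require_atom(fixed).coord, rotated.require_atom(fixed).coord
            )
        for name in ("ND1", "CD2", "CE1", "NE2"):
            d0 = np.linalg.norm(his.require_atom(name).coord - his.require_atom("CG").coord)
            d1 = np.linalg.norm(rotated.require_atom(name).coord - rotated.require_atom("CG").coord)
            assert d0 == pytest.approx(d1, abs=1e-9)
        np.testing.assert_allclose(
            rotate_his_chi2(his, 0.0).require_atom("NE2").coord,
            his.require_atom("NE2").coord,
        )

    def test_twisted_his_recovered(self):
        spec = SiteSpec(("HIS", "HIS", "GLU", "CYS"), "tetrahedral",
                        his_twist=(45.0, 0.0))
        s = make_ideal_site(spec, zinc_coord=(0, 0, 0))
        start = initial_zinc_estimate(s.residues)[0]
        chosen = select_binding_atoms(s.residues, start)
        unsampled = refine_zinc_position(chosen, start)
        unsampled_score = site_his_angles_score(chosen, unsampled.zinc_coord)
        result = sample_his_rotamers(s.residues, start)
        assert result.angles_score < unsampled_score
        alphas = [a.alpha for a in result.his_angles]
        assert max(alphas) <= 15.0 + 1e-6

    def test_ideal_configuration_unchanged(self):
        spec = SiteSpec(("HIS", "HIS", "GLU", "CYS"), "tetrahedral")
        s = make_ideal_site(spec, zinc_coord=(0, 0, 0))
        start = initial_zinc_estimate(s.residues)[0]
        result = sample_his_rotamers(s.residues, start)
        assert result.rotations == (0.0, 0.0)
        # one greedy round: base + at most 3^2 - 1 proposals
        assert result.n_evaluations <= 9

    def test_never_worse_than_unsampled(self):
        for seed in range(5):
            spec = SiteSpec(("HIS", "HIS", "HIS"), "trigonal_apex")
            s = make_ideal_site(spec, zinc_coord=(0, 0, 0))
            s = fixtures.perturb_site(s, 0.25, seed=seed)
            starts = initial_zinc_estimate(s.residues)
            start = starts[0]
            chosen = select_binding_atoms(s.residues, start)
            placed = refine_zinc_position(chosen, start)
            base = site_his_angles_score(chosen, placed.zinc_coord)
            result = sample_his_rotamers(s.residues, start)
            assert result.angles_score <= base + 1e-9

    def test_visited_bound_two_his(self):
        spec = SiteSpec(("HIS", "HIS", "GLU", "CYS"), "tetrahedral",
                        his_twist=(60.0, -30.0))
        s = make_ideal_site(spec, zinc_coord=(0, 0, 0))
        start = initial_zinc_estimate(s.residues)[0]
        result = sample_his_rotamers(s.residues, start)
        assert result.n_evaluations <= len(result.visited) <= 25**2
        assert all(abs(r) <= 180.0 for rot in result.visited for r in rot)

    def test_no_his_pass_through(self):
        spec = SiteSpec(("ASP", "GLU", "SER"), "trigonal_apex")
        s = make_ideal_site(spec, zinc_coord=(0, 0, 0))
        start = initial_zinc_estimate(s.residues)[0]
        result = sample_his_rotamers(s.residues, start)
        assert result.rotations == ()
        assert result.n_evaluations == 1
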