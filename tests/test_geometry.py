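"""Backbone math: internal-coordinate construction, dihedrals, superposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldsmith.geometry import (
    BOND_C_N,
    BOND_CA_C,
    BOND_N_CA,
    count_clashes,
    dihedral,
    helix_bend,
    is_undefined,
    measure_torsions,
    superpose_rmsd,
    torsions_to_coords,
)
from foldsmith.fixtures import FixtureSpec, make_fixture

from conftest import apply_rigid, random_rotation_translation

HELIX = (-57.0, -47.0, 180.0)
EXTENDED = (180.0, 180.0, 180.0)


def angdiff(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


# --------------------------------------------------------------------------
# independent forward-kinematics oracle (rotation-matrix NeRF, written
# separately from the implementation under test)


def _oracle_place(a, b, c, bond, angle, torsion):
    a, b, c = np.asarray(a), np.asarray(b), np.asarray(c)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    frame = np.stack([bc, m, n], axis=1)
    return c + frame @ d


def _oracle_backbone(torsions):
    n = len(torsions)
    N = [np.zeros(3)]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(111.2)
    C = [CA[0] + np.array([-BOND_CA_C * math.cos(ang), BOND_CA_C * math.sin(ang), 0.0])]
    for i in range(n - 1):
        psi, omega = torsions[i][1], torsions[i][2]
        phi_next = torsions[i + 1][0]
        N.append(_oracle_place(N[i], CA[i], C[i], BOND_C_N, 116.2, psi))
        CA.append(_oracle_place(CA[i], C[i], N[i + 1], BOND_N_CA, 121.7, omega))
        C.append(_oracle_place(C[i], N[i + 1], CA[i + 1], BOND_CA_C, 111.2, phi_next))
    return np.array(N), np.array(CA), np.array(C)


class TestTorsionsToCoords:
    def test_helix_ca_spacing_matches_oracle(self):
        chain = torsions_to_coords([HELIX] * 12)
        ca = chain.ca_coords()
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.05)
        _, ca_oracle, _ = _oracle_backbone([HELIX] * 12)
        assert np.allclose(ca, ca_oracle, atol=1e-8)

    def test_round_trip_identity(self):
        tl = [(-57.0, -47.0, 180.0), (-135.0, 135.0, 179.0), (60.0, 40.0, -178.0),
              (70.0, 170.0, 180.0), (-60.0, -40.0, 175.0), (-100.0, 120.0, 180.0)]
        chain = torsions_to_coords(tl)
        measured = measure_torsions(chain)
        for i in range(1, len(tl) - 1):
            for k in range(3):
                assert angdiff(measured[i][k], tl[i][k]) < 1e-6

    def test_extended_longer_than_helix(self):
        helix = torsions_to_coords([HELIX] * 12)
        ext = torsions_to_coords([EXTENDED] * 12)

        def e2e(c):
            ca = c.ca_coords()
            return np.linalg.norm(ca[-1] - ca[0])

        assert e2e(ext) > e2e(helix)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            torsions_to_coords([HELIX])
        with pytest.raises(ValueError):
            torsions_to_coords([HELIX, (math.nan, 0.0, 180.0), HELIX])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(
            st.floats(-179.9, 180.0), st.floats(-179.9, 180.0),
            st.floats(-179.9, 180.0)),
        min_size=3, max_size=12,
    ))
    def test_round_trip_property(self, tl):
        chain = torsions_to_coords(tl)
        measured = measure_torsions(chain)
        for i in range(len(tl)):
            for k, val in enumerate(measured[i]):
                if is_undefined(val):
                    continue
                assert angdiff(val, tl[i][k]) < 1e-6


class TestMeasureTorsions:
    def test_degenerate_collinear_gives_sentinel(self):
        # four collinear atoms: dihedral undefined, no crash
        assert is_undefined(dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]))

    def test_planar_zigzag_is_180(self):
        p1, p2, p3, p4 = [0, 1, 0], [1, 0, 0], [2, 1, 0], [3, 0, 0]
        assert angdiff(dihedral(p1, p2, p3, p4), 180.0) < 1e-9

    def test_chain_break_flagged(self, ideal_helix12):
        broken = ideal_helix12.copy()
        broken.coords[6:] += np.array([50.0, 0.0, 0.0])
        measured = measure_torsions(broken)
        assert broken.breaks == [6]
        assert is_undefined(measured[5][1])  # psi spanning the break


class TestDihedral:
    def test_cis_planar_is_zero(self):
        assert abs(dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0])) < 1e-9

    def test_trans_planar_is_180(self):
        val = dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0])
        assert angdiff(val, 180.0) < 1e-9

    def test_matches_bruteforce_oracle(self, rng):
        def oracle(p1, p2, p3, p4):
            # project the flanking bonds off the central axis, then atan2
            b0, b1, b2 = p1 - p2, p3 - p2, p4 - p3
            b1 = b1 / np.linalg.norm(b1)
            v = b0 - np.dot(b0, b1) * b1
            w = b2 - np.dot(b2, b1) * b1
            return math.degrees(math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))

        for _ in range(100):
            pts = rng.uniform(-5, 5, size=(4, 3))
            got = dihedral(*pts)
            want = oracle(*pts)
            if is_undefined(got):
                continue
            assert angdiff(got, want) < 1e-9


class TestSuperpose:
    def test_self_is_zero(self, rng):
        A = rng.uniform(-10, 10, size=(8, 3))
        rmsd, R, t = superpose_rmsd(A, A)
        assert rmsd < 1e-9
        assert abs(np.linalg.det(R) - 1.0) < 1e-9

    def test_rigid_invariance(self, rng):
        A = rng.uniform(-10, 10, size=(10, 3))
        Rm, tv = random_rotation_translation(rng)
        B = A @ Rm.T + tv
        rmsd, _, _ = superpose_rmsd(A, B)
        assert rmsd < 1e-9

    def test_single_displacement_closed_form(self, rng):
        # displacing one point of a large cloud by d gives rmsd ~ d/sqrt(n)
        # in the large-n limit; assert against the exact optimum computed by
        # scipy as an independent check, and the closed form loosely
        n, d = 400, 0.5
        A = rng.uniform(-10, 10, size=(n, 3))
        B = A.copy()
        B[0] += [d, 0, 0]
        rmsd, _, _ = superpose_rmsd(A, B)
        assert abs(rmsd - d / math.sqrt(n)) < 0.15 * d / math.sqrt(n)
        from scipy.spatial.transform import Rotation

        _, scipy_rssd = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
        assert abs(rmsd - scipy_rssd / math.sqrt(n)) < 1e-9

    def test_symmetry(self, rng):
        A = rng.uniform(-5, 5, size=(6, 3))
        B = rng.uniform(-5, 5, size=(6, 3))
        assert abs(superpose_rmsd(A, B)[0] - superpose_rmsd(B, A)[0]) < 1e-9

    def test_cardinality_mismatch(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestHelixBend:
    def test_ideal_helix_is_straight(self, ideal_helix12):
        assert helix_bend(ideal_helix12, 1, 12) < 2.0

    @pytest.mark.parametrize("angle", [10.0, 20.0, 30.0])
    def test_constructed_kink_recovered(self, angle):
        fx = make_fixture(FixtureSpec("kinked-helix", length=20, kink_angle=angle))
        measured = helix_bend(fx.chain, 1, len(fx.chain))
        assert abs(measured - angle) < 3.0

    def test_rigid_invariance(self, ideal_helix12, rng):
        fx = make_fixture(FixtureSpec("kinked-helix", length=20, kink_angle=20))
        R, t = random_rotation_translation(rng)
        moved = apply_rigid(fx.chain, R, t)
        a = helix_bend(fx.chain, 1, len(fx.chain))
        b = helix_bend(moved, 1, len(moved))
        assert abs(a - b) < 1e-6

    def test_double_length_straight_helix_matches_single(self):
        short = torsions_to_coords([HELIX] * 12)
        long = torsions_to_coords([HELIX] * 24)
        a = helix_bend(short, 1, 12)
        b = helix_bend(long, 1, 24)
        assert abs(a - b) < 1.0

    def test_too_short_gives_sentinel(self, ideal_helix12):
        assert is_undefined(helix_bend(ideal_helix12, 1, 7))


class TestClashes:
    def test_ideal_helix_clean_matches_oracle(self, ideal_helix12):
        # brute-force pairwise scan
        coords = ideal_helix12.coords
        n = len(coords)
        count = 0
        for i in range(n):
            for j in range(i + 2, n):
                for ai in range(4):
                    for aj in range(4):
                        if np.linalg.norm(coords[i, ai] - coords[j, aj]) < 2.5:
                            count += 1
        assert count == 0
        assert count_clashes(ideal_helix12, 2.5) == count

    def test_superposed_helices_clash(self, ideal_helix12):
        doubled = ideal_helix12.copy()
        coords = np.concatenate([doubled.coords, doubled.coords + 0.3])
        from foldsmith.geometry import BackboneChain

        merged = BackboneChain(coords, np.zeros(len(coords)), np.zeros(len(coords)),
                               np.zeros(len(coords)))
        assert count_clashes(merged, 2.5) > 0

    def test_zero_cutoff_is_empty(self, ideal_helix12):
        assert count_clashes(ideal_helix12, 0.0) == 0
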