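"""Superposition, torsions, ABEGO classification, helix construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from helixfuse.geometry import (
    RigidTransform,
    abego_letter,
    abego_string,
    average_models,
    dihedral,
    dihedrals,
    ideal_helix,
    kabsch,
    kabsch_rmsd_batch,
    radius_of_gyration,
    transform_model,
)


def random_rigid(rng):
    q = rng.normal(size=4)
    return RigidTransform(Rotation.from_quat(q / np.linalg.norm(q)).as_matrix(), rng.normal(0, 10, 3))


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(6, 3))
        tr, rmsd = kabsch(pts, pts)
        assert rmsd < 1e-12
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self, rng):
        pts = rng.normal(size=(8, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
        _, rmsd = kabsch(pts, moved)
        assert rmsd < 1e-9

    def test_matches_numerical_minimization_oracle(self, rng):
        """Optimal RMSD agrees with direct minimization over rotations."""
        mobile = rng.normal(size=(4, 3))
        target = mobile.copy()
        target[0] += np.array([1.0, 0.0, 0.0])
        _, rmsd = kabsch(mobile, target)

        P = mobile - mobile.mean(axis=0)
        Q = target - target.mean(axis=0)

        def cost(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            d = P @ R.T - Q
            return np.sqrt((d * d).sum() / len(P))

        best = np.inf
        for x0 in rng.normal(0, 1.5, size=(12, 3)):
            r = minimize(cost, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, r.fun)
        assert rmsd == pytest.approx(best, abs=1e-3)
        assert rmsd <= best + 1e-9  # never worse than the oracle's optimum

    def test_cross_check_against_scipy(self, rng):
        mobile = rng.normal(size=(10, 3))
        target = rng.normal(size=(10, 3))
        _, rmsd = kabsch(mobile, target)
        P = mobile - mobile.mean(axis=0)
        Q = target - target.mean(axis=0)
        _, rssd = Rotation.align_vectors(Q, P)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-9)

    def test_symmetry_and_rigid_invariance(self, rng):
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        _, r_ab = kabsch(a, b)
        _, r_ba = kabsch(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        moved = random_rigid(rng).apply(a)
        _, r_mb = kabsch(moved, b)
        assert r_mb == pytest.approx(r_ab, abs=1e-9)

    def test_batch_agrees_with_single(self, rng):
        mobile = rng.normal(size=(5, 12, 3))
        target = rng.normal(size=(5, 12, 3))
        batch = kabsch_rmsd_batch(mobile, target)
        singles = [kabsch(m, t)[1] for m, t in zip(mobile, target)]
        assert np.allclose(batch, singles, atol=1e-9)

    def test_degenerate_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            kabsch(line, line)
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDihedrals:
    def test_analytic_right_angle(self):
        # IUPAC: clockwise rotation of the far half-plane, viewed from p1
        # toward p2, is positive — i.e. a right-handed rotation about the
        # p1->p2 axis produces the NEGATIVE angle
        p1, p2 = np.zeros(3), np.array([0.0, 0.0, 1.5])
        p0 = p1 + np.array([1.4, 0.0, -0.5])
        arm = np.array([1.4, 0.0, 0.5])
        R = Rotation.from_rotvec(np.radians(90) * np.array([0.0, 0.0, 1.0])).as_matrix()
        assert dihedral(p0, p1, p2, p2 + R.T @ arm) == pytest.approx(90.0, abs=1e-6)
        assert dihedral(p0, p1, p2, p2 + R @ arm) == pytest.approx(-90.0, abs=1e-6)

    def test_ideal_helix_torsions(self):
        torsions = dihedrals(ideal_helix(10))
        assert torsions[0].phi is None and torsions[-1].psi is None
        for t in torsions[1:-1]:
            assert t.phi == pytest.approx(-57.0, abs=1.0)
            assert t.psi == pytest.approx(-47.0, abs=1.0)
            assert abs(t.omega) == pytest.approx(180.0, abs=1.0)

    def test_torsions_invariant_to_rigid_motion(self, rng):
        h = ideal_helix(8)
        moved = transform_model(h, random_rigid(rng))
        for a, b in zip(dihedrals(h)[1:-1], dihedrals(moved)[1:-1]):
            assert a.phi == pytest.approx(b.phi, abs=1e-6)
            assert a.psi == pytest.approx(b.psi, abs=1e-6)


class TestAbego:
    @pytest.mark.parametrize(
        "phi,psi,omega,letter",
        [
            (-57.0, -47.0, 180.0, "A"),
            (-120.0, 130.0, 180.0, "B"),
            (60.0, 30.0, 180.0, "G"),
            (60.0, 150.0, 180.0, "E"),
            (-57.0, -47.0, 0.0, "O"),  # cis peptide wins regardless of phi/psi
            (-75.0, 50.0, 180.0, "A"),  # psi boundary inclusive on the A side
            (-75.0, 50.1, 180.0, "B"),
        ],
    )
    def test_bin_table(self, phi, psi, omega, letter):
        assert abego_letter(phi, psi, omega) == letter

    @given(n=st.integers(min_value=3, max_value=40))
    @settings(max_examples=15, deadline=None)
    def test_ideal_helix_is_all_alpha(self, n):
        assert abego_string(ideal_helix(n)) == "A" * n


class TestIdealHelix:
    def test_ca_ca_distance(self):
        h = ideal_helix(2)
        d = np.linalg.norm(h.ca[1] - h.ca[0])
        assert 3.7 <= d <= 3.9

    def test_rise_over_ten_residues(self):
        h = ideal_helix(11)
        assert np.linalg.norm(h.ca[10] - h.ca[0]) == pytest.approx(15.0, abs=1.0)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            ideal_helix(0)


class TestAveraging:
    def test_average_of_identical_models(self, rng):
        h = ideal_helix(6)
        avg = average_models([h.copy(), h.copy(), h.copy()])
        assert np.abs(avg.coords - h.coords).max() < 1e-9

    def test_rigid_copies_average_to_original(self, rng):
        h = ideal_helix(6)
        moved = transform_model(h, random_rigid(rng))
        avg = average_models([h, moved])
        assert np.abs(avg.coords - h.coords).max() < 1e-6

    def test_symmetric_displacements_cancel(self):
        # cancellation is exact up to the superposition each model receives,
        # which perturbs coordinates only at second order in the displacement
        h = ideal_helix(6)
        d = 1e-4
        up, down = h.copy(), h.copy()
        up.coords[3, 1] += np.array([0.0, 0.0, d])
        down.coords[3, 1] -= np.array([0.0, 0.0, d])
        avg = average_models([h, up, down])
        assert np.abs(avg.coords - h.coords).max() < 1e-6

    def test_idempotent(self):
        h = ideal_helix(6)
        avg = average_models([h, h])
        again = average_models([avg, avg])
        assert np.abs(again.coords - avg.coords).max() < 1e-9

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            average_models([ideal_helix(5), ideal_helix(6)])


class TestRadiusOfGyration:
    def test_single_residue(self):
        assert radius_of_gyration(ideal_helix(1)) == 0.0

    def test_two_point_formula(self):
        h = ideal_helix(2)
        h.coords[0, 1] = np.array([0.0, 0.0, 0.0])
        h.coords[1, 1] = np.array([4.0, 0.0, 0.0])
        assert radius_of_gyration(h) == pytest.approx(2.0, abs=1e-12)

    def test_direct_sum_oracle(self, bundle):
        ca = bundle.ca
        centroid = ca.mean(axis=0)
        expected = np.sqrt(sum(float((p - centroid) @ (p - centroid)) for p in ca) / len(ca))
        assert radius_of_gyration(bundle) == pytest.approx(expected, abs=1e-9)
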