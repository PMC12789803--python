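"""Geometry kernel tests against independent oracles.

The Kabsch superposition is checked against the quaternion (Horn)
eigenvalue method implemented separately here, and torsions against the
projection (praxeolitic) dihedral formula -- two formulations that share
no code with the implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from urimod.geometry import (CoordinateSet, CorrespondenceError,
                             GeometryError, UndefinedTorsionError,
                             kabsch_superpose, mean_coordinates,
                             representative_to_mean, torsion_angle)

from conftest import random_coordinate_set, random_rotation


# ---------------------------------------------------------------------------
# independent oracles

def quaternion_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum RMSD via Horn's quaternion eigenvalue method."""
    x0 = x - x.mean(axis=0)
    y0 = y - y.mean(axis=0)
    m = x0.T @ y0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (x0 ** 2).sum() + (y0 ** 2).sum()
    return float(np.sqrt(max(0.0, e0 - 2.0 * lam) / len(x)))


def dihedral_oracle(p1, p2, p3, p4) -> float:
    """Signed dihedral via the projection formula."""
    b1 = np.asarray(p1) - np.asarray(p2)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    b2n = b2 / np.linalg.norm(b2)
    u = b1 - np.dot(b1, b2n) * b2n
    w = b3 - np.dot(b3, b2n) * b2n
    ang = np.degrees(np.arctan2(np.dot(np.cross(b2n, u), w), np.dot(u, w)))
    return float(ang)


# ---------------------------------------------------------------------------
# torsions

class TestTorsion:
    def test_planar_cis_is_zero(self):
        assert torsion_angle([1, 1, 0], [0, 0, 0], [1, 0, 0], [2, 1, 0]) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert torsion_angle([1, 1, 0], [0, 0, 0], [1, 0, 0], [2, -1, 0]) == pytest.approx(180.0)

    def test_matches_projection_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3.0
            expected = dihedral_oracle(*pts)
            assert torsion_angle(*pts) == pytest.approx(expected, abs=1e-9)

    def test_reversal_invariance_and_mirror_antisymmetry(self):
        # the IUPAC dihedral is unchanged by reversing the atom chain and
        # negated by mirroring the coordinates
        rng = np.random.default_rng(5)
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            fwd = torsion_angle(*pts)
            assert torsion_angle(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)
            if abs(abs(fwd) - 180.0) > 1e-9:
                assert torsion_angle(*(-pts)) == pytest.approx(-fwd, abs=1e-9)

    def test_collinear_points_raise(self):
        with pytest.raises(UndefinedTorsionError):
            torsion_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_range_is_half_open(self):
        # trans arrangement must report +180, never -180
        val = torsion_angle([1, 1, 0], [0, 0, 0], [1, 0, 0], [2, -1, 0])
        assert val == 180.0


# ---------------------------------------------------------------------------
# Kabsch superposition

class TestKabsch:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(0)
        a = random_coordinate_set(rng, 12)
        sup = kabsch_superpose(a, a)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        a = random_coordinate_set(rng, 20)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        b = CoordinateSet(a.labels, a.coords @ rot.T + np.array([1.0, 2.0, 3.0]))
        sup = kabsch_superpose(a, b)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, rot, atol=1e-9)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(10, 100))
            a = rng.normal(size=(n, 3)) * 4.0
            b = a @ random_rotation(rng).T + rng.normal(size=3) * 3.0
            b += rng.normal(size=(n, 3)) * rng.uniform(0.0, 1.0)
            labels = tuple(range(n))
            sup = kabsch_superpose(CoordinateSet(labels, a),
                                   CoordinateSet(labels, b))
            assert sup.rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-6)

    def test_rmsd_symmetric_and_rigid_invariant(self):
        rng = np.random.default_rng(9)
        a = random_coordinate_set(rng, 30)
        noisy = CoordinateSet(a.labels, a.coords + rng.normal(size=(30, 3)) * 0.2)
        r_ab = kabsch_superpose(a, noisy).rmsd
        r_ba = kabsch_superpose(noisy, a).rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        rot = random_rotation(rng)
        moved = CoordinateSet(a.labels, noisy.coords @ rot.T + 7.0)
        assert kabsch_superpose(a, moved).rmsd == pytest.approx(r_ab, abs=1e-9)

    def test_rotation_is_always_proper(self):
        # near-planar sets tempt reflection solutions; determinant must stay +1
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=(10, 3))
            a[:, 2] *= 1e-4
            b = -a  # inversion: best proper fit is a 180-degree rotation
            labels = tuple(range(10))
            sup = kabsch_superpose(CoordinateSet(labels, a),
                                   CoordinateSet(labels, b))
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        a = random_coordinate_set(rng, 5, "a")
        b = random_coordinate_set(rng, 5, "b")
        with pytest.raises(CorrespondenceError):
            kabsch_superpose(a, b)

    def test_too_few_atoms_rejected(self):
        rng = np.random.default_rng(4)
        a = random_coordinate_set(rng, 2)
        with pytest.raises(GeometryError):
            kabsch_superpose(a, a)


# ---------------------------------------------------------------------------
# mean structures and representatives

class TestMeanAndRepresentative:
    def test_identical_members_converge_immediately(self):
        rng = np.random.default_rng(10)
        a = random_coordinate_set(rng, 15)
        res = mean_coordinates([a, a, a])
        assert res.converged
        assert np.allclose(res.mean.coords, a.coords, atol=1e-9)

    def test_mean_of_rigid_copies_is_congruent(self):
        rng = np.random.default_rng(11)
        a = random_coordinate_set(rng, 15)
        rot = random_rotation(rng)
        b = CoordinateSet(a.labels, a.coords @ rot.T + 4.0)
        res = mean_coordinates([a, b])
        assert res.converged
        assert kabsch_superpose(res.mean, a).rmsd == pytest.approx(0.0, abs=1e-6)

    def test_mean_approaches_truth_with_noise(self):
        rng = np.random.default_rng(12)
        truth = random_coordinate_set(rng, 25)
        members = [CoordinateSet(truth.labels,
                                 truth.coords + rng.normal(size=(25, 3)) * 0.3)
                   for _ in range(10)]
        res = mean_coordinates(members)
        # tight-convergence re-run as oracle
        oracle = mean_coordinates(members, tol=1e-8, max_iter=200)
        assert kabsch_superpose(res.mean, oracle.mean).rmsd < 1e-3
        dev = kabsch_superpose(res.mean, truth).rmsd
        assert dev < 0.3 / np.sqrt(10) * 3.0

    def test_single_member(self):
        rng = np.random.default_rng(13)
        a = random_coordinate_set(rng, 8)
        res = representative_to_mean([a])
        assert res.index == 0
        assert res.rmsds == (0.0,)

    def test_low_noise_member_is_selected(self):
        rng = np.random.default_rng(14)
        truth = random_coordinate_set(rng, 30)
        members = []
        for i in range(6):
            sigma = 0.01 if i == 3 else 0.5
            members.append(CoordinateSet(
                truth.labels, truth.coords + rng.normal(size=(30, 3)) * sigma))
        res = representative_to_mean(members)
        assert res.index == 3
        # brute-force oracle: recompute every member's RMSD to the mean
        mean = mean_coordinates(members).mean
        oracle = [kabsch_superpose(m, mean).rmsd for m in members]
        assert res.index == int(np.argmin(oracle))

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(15)
        a = random_coordinate_set(rng, 10)
        rot = random_rotation(rng)
        b = CoordinateSet(a.labels, a.coords @ rot.T + 1.0)
        res = representative_to_mean([a, b])
        assert res.index == 0
        assert res.tie

    def test_order_invariance_up_to_tiebreak(self):
        rng = np.random.default_rng(16)
        truth = random_coordinate_set(rng, 20)
        members = [CoordinateSet(truth.labels,
                                 truth.coords + rng.normal(size=(20, 3)) * 0.4)
                   for _ in range(5)]
        res = representative_to_mean(members)
        perm = [2, 0, 4, 1, 3]
        res_p = representative_to_mean([members[i] for i in perm])
        assert perm[res_p.index] == res.index


@settings(max_examples=30, derandomize=True)
@given(st.integers(min_value=3, max_value=40), st.integers(min_value=0, max_value=10**6))
def test_rmsd_nonnegative_and_symmetric(n, seed):
    rng = np.random.default_rng(seed)
    labels = tuple(range(n))
    a = CoordinateSet(labels, rng.normal(size=(n, 3)))
    b = CoordinateSet(labels, rng.normal(size=(n, 3)))
    r = kabsch_superpose(a, b).rmsd
    assert r >= 0.0
    assert kabsch_superpose(b, a).rmsd == pytest.approx(r, abs=1e-9)
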