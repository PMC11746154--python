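"""Superposition, rotations, axes and distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spo11dock.bdna import HelixParams, build_bform_duplex
from spo11dock.geometry import (
    AxisLine,
    RigidTransform,
    atom_distance,
    axis_offset,
    fit_helical_axis,
    interaxis_angle,
    kabsch,
    paired_nucleotides,
    rotation_angle,
    superpose_structures,
)
from spo11dock.structures import Sel, concat
from spo11dock.synthetic import make_perturbed_pair


def random_rigid(rng) -> RigidTransform:
    return RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                          rng.uniform(-10, 10, 3))


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        res = kabsch(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        t = RigidTransform.about_axis([0, 0, 1], 90.0)
        t = RigidTransform(t.rotation, np.array([1.0, 2.0, 3.0]))
        res = kabsch(pts, t.apply(pts))
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        inv = t.inverse()
        np.testing.assert_allclose(res.transform.rotation, inv.rotation, atol=1e-9)
        np.testing.assert_allclose(res.transform.translation, inv.translation,
                                   atol=1e-9)

    def test_optimality_vs_randomized_brute_force(self):
        """No random rigid transform beats the closed-form optimum."""
        rng = np.random.default_rng(2)
        P = rng.normal(size=(6, 3))
        Q = rng.normal(size=(6, 3))
        best = kabsch(P, Q)
        for _ in range(20000):
            t = random_rigid(rng)
            rmsd = np.sqrt(np.mean(np.sum((t.apply(Q) - P) ** 2, axis=1)))
            assert rmsd >= best.rmsd - 1e-9

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(12, 3))
        Q = rng.normal(size=(12, 3)) * 0.3 + P
        ours = kabsch(P, Q)
        rot, rssd = Rotation.align_vectors(P - P.mean(0), Q - Q.mean(0))
        np.testing.assert_allclose(ours.transform.rotation, rot.as_matrix(),
                                   atol=1e-8)
        assert ours.rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-8)

    def test_never_returns_reflection(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(5, 3))
        res = kabsch(P, P * np.array([-1, 1, 1]))  # mirrored cloud
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_invariant_under_pretransform(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(9, 3))
        Q = P + rng.normal(0, 0.4, size=(9, 3))
        base = kabsch(P, Q).rmsd
        for seed in range(5):
            t = random_rigid(np.random.default_rng(seed))
            assert kabsch(P, t.apply(Q)).rmsd == pytest.approx(base, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRotationAngle:
    def test_identity_is_zero(self):
        assert rotation_angle(RigidTransform.identity())[0] == 0.0

    @pytest.mark.parametrize("angle", [30.0, 90.0, 179.0])
    def test_recovers_angle_about_random_axis(self, angle):
        rng = np.random.default_rng(int(angle))
        axis = rng.normal(size=3)
        t = RigidTransform.about_axis(axis, angle)
        got, got_axis = rotation_angle(t)
        assert got == pytest.approx(angle, abs=1e-9)
        np.testing.assert_allclose(got_axis, axis / np.linalg.norm(axis),
                                   atol=1e-6)

    def test_composition_about_same_axis_adds(self):
        a, b = 140.0, 100.0  # 240 folds to 120
        axis = [1.0, 2.0, -1.0]
        t = RigidTransform.about_axis(axis, a) @ RigidTransform.about_axis(axis, b)
        assert rotation_angle(t)[0] == pytest.approx(120.0, abs=1e-9)

    def test_transform_times_inverse_is_zero(self):
        t = RigidTransform.about_axis([3, 1, 2], 77.0)
        t = RigidTransform(t.rotation, np.array([4.0, -1.0, 2.0]))
        assert rotation_angle(t @ t.inverse())[0] == pytest.approx(0.0, abs=1e-6)


class TestSuperposeStructures:
    def test_self_superposition(self, fake_protein):
        res = superpose_structures(fake_protein, fake_protein)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_pairs == fake_protein.n_residues

    def test_perturbed_pair_within_calibrated_bounds(self, fake_protein):
        from conftest import make_fake_protein

        base = make_fake_protein(n_res=200, seed=11)
        for seed in range(5):
            _, moved, (lo, hi) = make_perturbed_pair(base, sigma=0.5, seed=seed)
            fit = superpose_structures(base, moved)
            assert lo <= fit.rmsd <= hi

    def test_too_few_shared_atoms_errors(self, fake_protein, duplex12):
        with pytest.raises(ValueError, match="C-alpha"):
            superpose_structures(fake_protein, duplex12)


class TestAxes:
    def test_straight_duplex_axis_parallel_to_z(self, duplex12):
        ax = fit_helical_axis(duplex12)
        assert interaxis_angle(ax, AxisLine([0, 0, 0], [0, 0, 1])) < 0.5

    def test_direction_flips_with_reference_strand(self, duplex12):
        a = fit_helical_axis(duplex12, "A")
        b = fit_helical_axis(duplex12, "B")
        assert np.dot(a.direction, b.direction) == pytest.approx(-1.0, abs=1e-6)

    def test_elbow_recovers_designed_angle(self):
        """Two duplexes joined at a designed 130-degree path elbow."""
        params = HelixParams()
        d1 = build_bform_duplex("ACGTACGTAC", params)
        elbow = RigidTransform.about_axis([1, 0, 0], 180.0 - 130.0,
                                          point=[0, 0, 0])
        d2 = build_bform_duplex("TTGCAATCGG", params).transformed(elbow)
        ax1 = fit_helical_axis(d1)
        ax2 = fit_helical_axis(d2)
        assert interaxis_angle(ax1, ax2) == pytest.approx(50.0, abs=1.0)

    def test_too_short_duplex_errors(self):
        with pytest.raises(ValueError):
            fit_helical_axis(build_bform_duplex("ACG"))

    def test_interaxis_angle_conventions(self):
        z = AxisLine([0, 0, 0], [0, 0, 1])
        assert interaxis_angle(z, z) == pytest.approx(0.0)
        x = AxisLine([0, 0, 0], [1, 0, 0])
        assert interaxis_angle(z, x) == pytest.approx(90.0)
        assert axis_offset(z, x) == pytest.approx(0.0)

    def test_axis_offset_skew_and_parallel(self):
        z = AxisLine([0, 0, 0], [0, 0, 1])
        x_off = AxisLine([0, 3, 7], [1, 0, 0])   # skew, offset 3 along y
        assert axis_offset(z, x_off) == pytest.approx(3.0)
        assert axis_offset(x_off, z) == pytest.approx(3.0)
        par = AxisLine([4, 3, 0], [0, 0, 1])
        assert axis_offset(z, par) == pytest.approx(5.0)

    def test_paired_nucleotides_full_register(self, duplex12):
        pairs = paired_nucleotides(duplex12)
        assert [(a.seq_id, b.seq_id) for a, b in pairs] == \
            [(i, 13 - i) for i in range(1, 13)]


class TestAtomDistance:
    def test_min_distance_matches_brute_force(self, duplex12):
        sel_a = Sel(chain_ids=("A",))
        sel_b = Sel(chain_ids=("B",))
        d = atom_distance(duplex12, sel_a, sel_b, mode="min")
        from spo11dock.structures import select

        xa = select(duplex12, sel_a).coords()
        xb = select(duplex12, sel_b).coords()
        brute = np.min(np.linalg.norm(xa[:, None] - xb[None], axis=2))
        assert d == pytest.approx(brute, abs=1e-12)

    def test_ca_ca_mode(self, fake_protein):
        d = atom_distance(fake_protein, Sel(seq_range=(1, 1)),
                          Sel(seq_range=(4, 4)), mode="ca-ca")
        p = fake_protein.residues
        expect = np.linalg.norm(p[0].atoms[0].coords - p[3].atoms[0].coords)
        assert d == pytest.approx(expect)
        with pytest.raises(ValueError, match="single-residue"):
            atom_distance(fake_protein, Sel(seq_range=(1, 2)),
                          Sel(seq_range=(4, 4)), mode="ca-ca")

    def test_empty_selection_errors(self, fake_protein):
        with pytest.raises(ValueError):
            atom_distance(fake_protein, Sel(chain_ids=("Q",)), Sel(),
                          mode="min")
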