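"""Double-end docking and the clash-vs-length scan, against independent
frame-algebra and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spo11dock.bdna import HelixParams, helix_step
from spo11dock.geometry import RigidTransform
from spo11dock.interfaces import ClashCriterion
from spo11dock.scan import (
    DockSpec,
    clash_vs_length_scan,
    dock_double_end,
    min_cooriented_clashfree,
)
from spo11dock.structures import Sel, select
from spo11dock.synthetic import ToyComplexSpec, make_toy_complex


def ideal_copy_transforms(toy, L, params):
    """Frame-algebra oracle: the toy complex is built in rail coordinates
    with its first paired bp at helix step `overhang`, so copy 1 is
    ``step^-overhang`` and copy 2 is ``step^(L-1) . flip . copy1``."""
    t1 = helix_step(params).power(-toy.spec.overhang)
    flip = RigidTransform.about_axis([1, 0, 0], 180.0)
    t2 = helix_step(params).power(L - 1) @ flip @ t1
    return t1, t2


def brute_force_scan(toy, lengths, params, cutoff):
    """All-pairs clash counts between the two envelope copies, placed by
    direct frame algebra (no Kabsch, no k-d tree)."""
    env = select(toy.structure, Sel(chain_ids=("E",))).coords()
    out = []
    for L in lengths:
        t1, t2 = ideal_copy_transforms(toy, L, params)
        a, b = t1.apply(env), t2.apply(env)
        d = np.linalg.norm(a[:, None] - b[None], axis=2)
        out.append(int(np.sum(2 * 1.70 - d >= cutoff)))
    return out


class TestDockDoubleEnd:
    def test_assembly_atom_count_doubles(self, toy_sphere, helix_params):
        docked = dock_double_end(DockSpec(toy_sphere.structure), 30, helix_params)
        assert docked.assembly.n_atoms == 2 * toy_sphere.structure.n_atoms

    def test_copy_transforms_match_frame_algebra(self, toy_sphere, helix_params):
        L = 30
        docked = dock_double_end(DockSpec(toy_sphere.structure), L, helix_params)
        t1, t2 = ideal_copy_transforms(toy_sphere, L, helix_params)
        np.testing.assert_allclose(docked.t1.rotation, t1.rotation, atol=1e-8)
        np.testing.assert_allclose(docked.t1.translation, t1.translation, atol=1e-8)
        np.testing.assert_allclose(docked.t2.rotation, t2.rotation, atol=1e-8)
        np.testing.assert_allclose(docked.t2.translation, t2.translation, atol=1e-8)

    def test_helical_period_preserves_orientation(self, toy_sphere, helix_params):
        d1 = dock_double_end(DockSpec(toy_sphere.structure), 30, helix_params)
        d2 = dock_double_end(DockSpec(toy_sphere.structure), 40, helix_params)
        assert d1.relative_rotation == pytest.approx(d2.relative_rotation, abs=1e-6)
        # the far copy moved exactly ten rises further
        rel = d2.t2 @ d1.t2.inverse()
        np.testing.assert_allclose(rel.rotation, np.eye(3), atol=1e-8)
        assert np.linalg.norm(rel.translation) == pytest.approx(
            10 * helix_params.rise, abs=1e-6)

    def test_too_short_rail_errors(self, toy_sphere, helix_params):
        with pytest.raises(ValueError):
            dock_double_end(DockSpec(toy_sphere.structure), 6, helix_params)


class TestScan:
    @pytest.mark.parametrize("cutoff", [0.4, 0.6])
    def test_matches_brute_force_and_analytic_onset(self, toy_sphere,
                                                    helix_params, cutoff):
        lengths = range(24, 36)
        scan = clash_vs_length_scan(
            DockSpec(toy_sphere.structure), lengths,
            ClashCriterion(overlap_cutoff=cutoff), helix_params)
        brute = brute_force_scan(toy_sphere, lengths, helix_params, cutoff)
        assert [r.n_clashes for r in scan] == brute
        onset = toy_sphere.truth[f"first_clash_free_L_cutoff_{cutoff}"]
        for r in scan:
            assert (r.n_clashes == 0) == (r.length >= onset)

    def test_far_apart_no_clashes(self, toy_sphere, helix_params):
        (res,) = clash_vs_length_scan(DockSpec(toy_sphere.structure), [100],
                                      params=helix_params)
        assert res.n_clashes == 0

    def test_monotone_tail(self, toy_sphere, helix_params):
        scan = clash_vs_length_scan(DockSpec(toy_sphere.structure),
                                    range(20, 60), params=helix_params)
        clashes = [r.n_clashes for r in scan]
        first_zero = clashes.index(0)
        assert all(c == 0 for c in clashes[first_zero:])

    def test_invariant_under_global_rigid_transform(self, toy_sphere,
                                                    helix_params):
        rng = np.random.default_rng(9)
        t = RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                           rng.uniform(-30, 30, 3))
        moved = toy_sphere.structure.transformed(t)
        lengths = range(26, 34)
        base = clash_vs_length_scan(DockSpec(toy_sphere.structure), lengths,
                                    params=helix_params)
        shifted = clash_vs_length_scan(DockSpec(moved), lengths,
                                       params=helix_params)
        assert [r.n_clashes for r in base] == [r.n_clashes for r in shifted]
        for a, b in zip(base, shifted):
            assert a.relative_rotation == pytest.approx(b.relative_rotation,
                                                        abs=1e-6)

    def test_relative_rotation_follows_helical_register(self, toy_sphere,
                                                        helix_params):
        scan = clash_vs_length_scan(DockSpec(toy_sphere.structure),
                                    range(20, 31), params=helix_params)
        for r in scan:
            expect = ((r.length - 1) * helix_params.twist) % 360.0
            expect = min(expect, 360.0 - expect)
            assert r.relative_rotation == pytest.approx(expect, abs=1e-6)

    def test_center_to_center_is_length_plus_overhangs(self, toy_sphere,
                                                       helix_params):
        scan = clash_vs_length_scan(DockSpec(toy_sphere.structure), [25, 31],
                                    params=helix_params)
        assert [r.center_to_center for r in scan] == [27, 33]


class TestMinCoorientedClashfree:
    def test_toy_recovers_analytic_minimum(self, toy_sphere, helix_params):
        scan = clash_vs_length_scan(DockSpec(toy_sphere.structure),
                                    range(20, 46), params=helix_params)
        min_l, qualifying = min_cooriented_clashfree(scan)
        assert min_l == toy_sphere.truth["min_cooriented_clash_free_L_cutoff_0.6"]
        steps = [b - a for a, b in zip(qualifying, qualifying[1:])]
        assert set(steps) == {round(360.0 / helix_params.twist)}

    def test_engineered_onset_brute_force(self, helix_params):
        """A smaller envelope moves the clash onset; the reported minimum
        equals an independent search over the scan records."""
        toy = make_toy_complex(ToyComplexSpec(radius=15.0, center_bp=4.0))
        scan = clash_vs_length_scan(DockSpec(toy.structure), range(10, 45),
                                    params=helix_params)
        min_l, _ = min_cooriented_clashfree(scan)
        brute = min(r.length for r in scan
                    if r.n_clashes == 0 and r.relative_rotation <= 18.0)
        assert min_l == brute
        assert min_l >= toy.truth["first_clash_free_L_cutoff_0.6"]

    def test_not_found_returns_none(self, toy_sphere, helix_params):
        scan = clash_vs_length_scan(DockSpec(toy_sphere.structure),
                                    range(20, 26), params=helix_params)
        min_l, qualifying = min_cooriented_clashfree(scan)
        assert min_l is None and qualifying == []

    @pytest.mark.parametrize("twist", [34.3, 36.0])
    def test_robust_across_twist(self, toy_sphere, twist):
        """The minimal co-oriented clash-free length shifts by at most one
        helical-period rounding between the two standard twists."""
        params = HelixParams(twist=twist)
        toy = make_toy_complex(ToyComplexSpec(), params=params)
        scan = clash_vs_length_scan(DockSpec(toy.structure), range(20, 50),
                                    params=params)
        min_l, qualifying = min_cooriented_clashfree(scan)
        assert min_l is not None
        onset = toy.truth["first_clash_free_L_cutoff_0.6"]
        assert onset <= min_l <= onset + round(360.0 / twist)
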