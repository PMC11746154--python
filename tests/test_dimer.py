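"""Pre-break dimer models: co-docked control and template-guided assembly."""

import numpy as np
import pytest

from spo11dock.bdna import HelixParams, build_bform_duplex
from spo11dock.dimer import (
    build_bform_codocked_dimer,
    build_topo6_templated_dimer,
    dimer_dna_geometry,
    load_mapping,
)
from spo11dock.geometry import RigidTransform, rotation_angle
from spo11dock.structures import Sel, select
from spo11dock.synthetic import (
    ToyComplexSpec,
    make_synthetic_dimer_template,
    make_toy_complex,
)


@pytest.fixture(scope="module")
def wrap_toy():
    return make_toy_complex(ToyComplexSpec(envelope="wrap", radius=12.0,
                                           pitch=30.0, arc_deg=540.0))


@pytest.fixture(scope="module")
def templated(wrap_toy):
    tpl, mapping, prot, split, transforms = make_synthetic_dimer_template(wrap_toy)
    result = build_topo6_templated_dimer(wrap_toy.structure, tpl, split,
                                         mapping, prot)
    return result, transforms


class TestCodockedControl:
    def test_end_capping_envelope_clashes(self, wrap_toy):
        res = build_bform_codocked_dimer(wrap_toy.structure)
        assert res.protein_protein.n_clashes > 0
        assert res.protein_dna.n_clashes > 0
        assert res.clash_report.n_clashes == (res.protein_protein.n_clashes
                                              + res.protein_dna.n_clashes)

    def test_small_envelope_control_is_clash_free(self):
        small = make_toy_complex(ToyComplexSpec(radius=6.0, center_bp=8.0))
        res = build_bform_codocked_dimer(small.structure)
        assert res.clash_report.n_clashes == 0

    def test_blunt_complex_errors(self):
        blunt = make_toy_complex(ToyComplexSpec(overhang=0))
        with pytest.raises(ValueError, match="overhang"):
            build_bform_codocked_dimer(blunt.structure)

    def test_continuous_rail_dna_is_straight(self, wrap_toy):
        """The two DNA copies sit on one duplex path: 180 degrees, no
        offset."""
        res = build_bform_codocked_dimer(wrap_toy.structure)
        dna1 = select(res.copy1, Sel(polymer=("nucleotide",)))
        dna2 = select(res.copy2, Sel(polymer=("nucleotide",)))
        angle, offset, _ = dimer_dna_geometry(dna1, dna2)
        assert angle == pytest.approx(180.0, abs=1e-6)
        assert offset == pytest.approx(0.0, abs=1e-6)


class TestTemplatedDimer:
    def test_exact_recovery_of_construction(self, templated):
        result, transforms = templated
        m = result.metrics
        assert m.rmsd_N == pytest.approx(0.0, abs=1e-9)
        assert m.rmsd_C == pytest.approx(0.0, abs=1e-9)
        assert m.wh_rotation == pytest.approx(45.0, abs=1e-6)
        assert m.inter_dna_angle == pytest.approx(150.0, abs=1e-6)
        assert m.axis_offset == pytest.approx(5.0, abs=1e-6)

    def test_wh_rotation_consistent_with_transforms(self, templated):
        result, _ = templated
        t_n, t_c = result.transforms_N[0], result.transforms_C[0]
        assert result.metrics.wh_rotation == pytest.approx(
            rotation_angle(t_n @ t_c.inverse())[0], abs=1e-9)

    def test_end_separation_matches_direct_computation(self, wrap_toy,
                                                       templated):
        """Oracle: transform the known end atoms by the construction
        transforms and measure directly."""
        result, transforms = templated
        (t_n1, _), (t_n2, _) = transforms
        cx = wrap_toy.structure
        ref = [r for r in cx.residues
               if r.chain_id == "A" and r.polymer_class == "nucleotide"]
        five = next(r.atom("P").coords for r in ref if r.atom("P") is not None)
        rec = [r for r in cx.residues
               if r.chain_id == "B" and r.polymer_class == "nucleotide"]
        three = rec[-1].atom("C1'").coords
        d12 = np.linalg.norm(t_n1.apply(five) - t_n2.apply(three))
        d21 = np.linalg.norm(t_n2.apply(five) - t_n1.apply(three))
        assert result.metrics.end_separation == pytest.approx(
            0.5 * (d12 + d21), abs=1e-9)

    def test_eliminates_codocked_clashes(self, wrap_toy, templated):
        result, _ = templated
        control = build_bform_codocked_dimer(wrap_toy.structure)
        assert result.metrics.n_clashes < control.clash_report.n_clashes
        assert result.metrics.n_clashes == 0

    def test_identity_template_gives_zero_metrics(self, wrap_toy):
        """Templating onto a template whose first protomer is the complex
        itself recovers the identity: zero RMSD, zero rotation."""
        tpl, mapping, prot, split, _ = make_synthetic_dimer_template(
            wrap_toy, wh_rotation_deg=0.0)
        res = build_topo6_templated_dimer(wrap_toy.structure, tpl, split,
                                          mapping, prot)
        assert res.metrics.rmsd_N == pytest.approx(0.0, abs=1e-9)
        assert res.metrics.rmsd_C == pytest.approx(0.0, abs=1e-9)
        assert res.metrics.wh_rotation == pytest.approx(0.0, abs=1e-6)

    def test_deterministic(self, wrap_toy):
        tpl, mapping, prot, split, _ = make_synthetic_dimer_template(wrap_toy)
        a = build_topo6_templated_dimer(wrap_toy.structure, tpl, split,
                                        mapping, prot).metrics
        b = build_topo6_templated_dimer(wrap_toy.structure, tpl, split,
                                        mapping, prot).metrics
        assert a == b

    def test_sparse_mapping_errors(self, wrap_toy):
        tpl, mapping, prot, split, _ = make_synthetic_dimer_template(wrap_toy)
        thin = [r for r in mapping if r.complex_chain == "A"][:2]
        with pytest.raises(ValueError, match="atom pairs"):
            build_topo6_templated_dimer(wrap_toy.structure, tpl, split,
                                        thin, prot)


class TestDimerDnaGeometry:
    def test_colinear_head_to_tail(self):
        params = HelixParams()
        d1 = build_bform_duplex("ACGTACGTAC", params)
        flip = RigidTransform.about_axis([1, 0, 0], 180.0)
        shift = RigidTransform.translation_of([0, 0, -3.38])
        d2 = d1.transformed(shift @ flip)
        angle, offset, _ = dimer_dna_geometry(d1, d2)
        assert angle == pytest.approx(180.0, abs=1e-6)
        assert offset == pytest.approx(0.0, abs=1e-6)

    def test_constructed_elbow(self):
        params = HelixParams()
        d1 = build_bform_duplex("ACGTACGTAC", params)
        # V of 120 degrees: rotate a flipped copy so the oriented axes
        # (both pointing away from the junction at the origin) open at 120
        flip = RigidTransform.about_axis([1, 0, 0], 180.0)
        bend = RigidTransform.about_axis([1, 0, 0], -(180.0 - 120.0))
        d2 = d1.transformed(bend @ flip)
        angle, _, _ = dimer_dna_geometry(d1, d2)
        assert angle == pytest.approx(120.0, abs=1.0)


def test_mapping_loader_round_trip(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text(
        "# complex -> template residue mapping\n"
        "complex_chain\tcomplex_seq_id\ttemplate_chain\ttemplate_seq_id\n"
        "A\t135\tC\t106\n"
        "A\t288\tC\t249\n")
    rows = load_mapping(path)
    assert len(rows) == 2
    assert rows[0].complex_chain == "A" and rows[0].template_seq == 106

    empty = tmp_path / "empty.tsv"
    empty.write_text(
        "complex_chain\tcomplex_seq_id\ttemplate_chain\ttemplate_seq_id\n")
    with pytest.raises(ValueError, match="empty"):
        load_mapping(empty)
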