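"""Pre-break dimer modeling: B-form co-docking and template-guided assembly.

Two analyses of how a pair of DNA-end-bound complexes could assemble into
the dimer that makes a double-strand break:

1. ``build_bform_codocked_dimer`` places two copies of the complex on one
   continuous B-form rail in the break register (the first 5'-overhang
   nucleotide of one copy one nucleotide away from the other copy's
   recessed 3' end).  For the real complexes this configuration is
   sterically impossible -- the winged-helix (WH) domain of each catalytic
   subunit collides with the partner's Toprim domain -- and the resulting
   clash report localizes those collisions.

2. ``build_topo6_templated_dimer`` instead splits each complex between the
   WH and Toprim domains of the catalytic subunit (the linker between them
   is flexible) and rigid-body-aligns the two parts independently onto
   their cognate domains in the two protomers of a type IIB topoisomerase
   dimer template.  The DNA travels with the WH-domain part, preserving
   the protein-DNA contacts.  The returned metrics quantify the alignment
   (per-part RMSDs), the implied WH-vs-Toprim rotation, the residual
   inter-protomer clashes, and the geometry of the juxtaposed DNA ends
   (V-shape angle, helical-axis offset, 5'-to-3' end separation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bdna import HelixParams, build_bform_duplex
from .geometry import (
    AxisLine,
    RigidTransform,
    axis_offset,
    fit_helical_axis,
    interaxis_angle,
    kabsch,
    rotation_angle,
)
from .interfaces import ClashCriterion, ClashReport, count_clashes
from .scan import RAIL_CHAINS, DockSpec, _docking_transform, _pair_coords
from .structures import Residue, Sel, Selection, Structure, concat, select

__all__ = [
    "DomainSplit",
    "DimerMetrics",
    "MappingRow",
    "load_mapping",
    "build_bform_codocked_dimer",
    "build_topo6_templated_dimer",
    "dimer_dna_geometry",
    "CodockedDimer",
    "TemplatedDimer",
]


@dataclass
class DomainSplit:
    """Partition of a complex into a WH-side and a Toprim-side rigid body.

    ``part_N`` holds the catalytic subunit up to the domain boundary plus
    the subunits (and DNA) that move with the WH domain; ``part_C`` holds
    the rest.  The default boundary for the yeast catalytic subunit is
    between residues 172 and 173 (the flexible WH-Toprim linker).
    """

    part_N: Selection
    part_C: Selection
    boundary: tuple[int, int] = (172, 173)

    @classmethod
    def for_catalytic_chain(cls, chain: str, companions_N: tuple[str, ...],
                            companions_C: tuple[str, ...],
                            dna_chains: tuple[str, ...],
                            boundary: tuple[int, int] = (172, 173)) -> "DomainSplit":
        part_N = (Sel(chain_ids=(chain,), seq_range=(None, boundary[0]))
                  | Sel(chain_ids=tuple(companions_N) + tuple(dna_chains)))
        part_C = (Sel(chain_ids=(chain,), seq_range=(boundary[1], None))
                  | Sel(chain_ids=tuple(companions_C)))
        return cls(part_N=part_N, part_C=part_C, boundary=boundary)

    def check_partition(self, complex_: Structure) -> bool:
        n = select(complex_, self.part_N).n_atoms
        c = select(complex_, self.part_C).n_atoms
        return n + c == complex_.n_atoms and n > 0 and c > 0


@dataclass(frozen=True)
class DimerMetrics:
    """Geometric summary of a modeled dimer (angstrom / degrees)."""

    rmsd_N: float
    n_pairs_N: int
    rmsd_C: float
    n_pairs_C: int
    wh_rotation: float
    inter_dna_angle: float
    axis_offset: float
    end_separation: float
    n_clashes: int

    def as_dict(self) -> dict:
        return {
            "rmsd_N": self.rmsd_N, "n_pairs_N": self.n_pairs_N,
            "rmsd_C": self.rmsd_C, "n_pairs_C": self.n_pairs_C,
            "wh_rotation_deg": self.wh_rotation,
            "inter_dna_angle_deg": self.inter_dna_angle,
            "axis_offset_A": self.axis_offset,
            "end_separation_A": self.end_separation,
            "n_clashes": self.n_clashes,
        }


# ---------------------------------------------------------------------------
# B-form co-docked control
# ---------------------------------------------------------------------------

@dataclass
class CodockedDimer:
    assembly: Structure
    copy1: Structure
    copy2: Structure
    rail: Structure
    clash_report: ClashReport          # protein-protein + protein-vs-DNA
    protein_protein: ClashReport
    protein_dna: ClashReport


def _overhang_residues(complex_: Structure, spec: DockSpec) -> list[Residue]:
    """Unpaired 5' residues of the reference strand, preceding the duplex."""
    pairs = spec.anchor_pairs()
    ref_chain = pairs[0][0].chain_id
    first_paired_seq = pairs[0][0].seq_id
    return [r for r in complex_.residues
            if r.chain_id == ref_chain and r.polymer_class == "nucleotide"
            and r.seq_id < first_paired_seq]


def _split_clashes(copy1: Structure, copy2: Structure,
                   criterion: ClashCriterion):
    """Clash reports excluding DNA-DNA pairs (which overlap by design)."""
    prot = Sel(polymer=("protein", "ion", "other"))
    dna = Sel(polymer=("nucleotide",))
    pp = count_clashes(select(copy1, prot), select(copy2, prot), criterion)
    pd = count_clashes(select(copy1, prot), select(copy2, dna), criterion)
    dp = count_clashes(select(copy1, dna), select(copy2, prot), criterion)
    combined = ClashReport(pairs=pp.pairs + pd.pairs + dp.pairs)
    pd_all = ClashReport(pairs=pd.pairs + dp.pairs)
    return combined, pp, pd_all


def build_bform_codocked_dimer(complex_: Structure,
                               params: HelixParams | None = None,
                               criterion: ClashCriterion | None = None,
                               n_anchor_bp: int = 4,
                               reference_chain: str | None = None) -> CodockedDimer:
    """Dock two copies on one continuous B-form rail in the break register.

    The register places the first 5'-overhang nucleotide of each copy one
    nucleotide away from the other copy's recessed 3' end -- the relative
    position of the two duplex segments in an intact pre-break molecule cut
    with a two-nucleotide 5' stagger.  Clashes are reported between the two
    copies, protein-vs-protein and protein-vs-opposite-DNA (the two DNA
    copies occupy complementary positions of one duplex and are not counted
    against each other).
    """
    params = params or HelixParams()
    criterion = criterion or ClashCriterion()
    spec = DockSpec(complex_, n_anchor_bp=n_anchor_bp,
                    reference_chain=reference_chain)
    if not _overhang_residues(complex_, spec):
        raise ValueError(
            "complex has no traced 5'-overhang nucleotide on the reference "
            "strand; cannot establish the break register")
    # rail long enough to hold both duplex footprints at offset a = dup+1
    a = _count_duplex_bp(complex_, spec) + 1
    N = 2 * (a - 1) + 1
    rail = build_bform_duplex("A" * N, params, chain_ids=RAIL_CHAINS,
                              structure_id=f"codock-rail-{N}")
    t1 = _register_transform(spec, rail, N, offset=a, flipped=False)
    t2 = _register_transform(spec, rail, N, offset=a - 2, flipped=True)
    copy1 = complex_.transformed(t1)
    copy2 = complex_.transformed(t2).renamed_chains(
        {c: c + "2" for c in complex_.chain_ids})
    combined, pp, pd = _split_clashes(copy1, copy2, criterion)
    assembly = concat([copy1, copy2], id="bform-codocked-dimer")
    return CodockedDimer(assembly, copy1, copy2, rail, combined, pp, pd)


def _count_duplex_bp(complex_: Structure, spec: DockSpec) -> int:
    from .geometry import paired_nucleotides

    return len(paired_nucleotides(complex_, spec.reference_chain))


def _register_transform(spec: DockSpec, rail: Structure, N: int,
                        offset: int, flipped: bool) -> RigidTransform:
    """Dock the anchor with bp k of the bound duplex on rail bp offset±k."""
    fixed, mobile = [], []
    for k, (ref_res, par_res) in enumerate(spec.anchor_pairs()):
        bp = offset + k if not flipped else offset - k
        if not (0 <= bp < N):
            raise ValueError("rail too short for the requested register")
        s1 = rail.residue(RAIL_CHAINS[0], bp + 1)       # strand 1 seq = bp+1
        s2 = rail.residue(RAIL_CHAINS[1], N - bp)       # strand 2 partner
        rail_ref, rail_par = (s2, s1) if flipped else (s1, s2)
        for c_res, r_res in ((ref_res, rail_ref), (par_res, rail_par)):
            f, m = _pair_coords(c_res, r_res)
            fixed.extend(f)
            mobile.extend(m)
    if len(fixed) < 3:
        raise ValueError("anchor pairing yielded fewer than 3 atom pairs")
    return kabsch(np.array(fixed), np.array(mobile)).transform


# ---------------------------------------------------------------------------
# Template-guided dimer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappingRow:
    complex_chain: str
    complex_seq: int
    template_chain: str
    template_seq: int


def load_mapping(path: str | Path) -> list[MappingRow]:
    """Read a residue-mapping table.

    TSV with header columns ``complex_chain complex_seq_id template_chain
    template_seq_id``; comment lines start with ``#``.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t")
        for rec in reader:
            rows.append(MappingRow(rec["complex_chain"],
                                   int(rec["complex_seq_id"]),
                                   rec["template_chain"],
                                   int(rec["template_seq_id"])))
    if not rows:
        raise ValueError(f"{path}: empty mapping table")
    return rows


_ALIGN_ATOM_PREFERENCE = ("CA", "C1'", "P")


def _mapped_coords(complex_: Structure, template: Structure,
                   rows: list[MappingRow]):
    fixed, mobile = [], []
    for row in rows:
        t_res = template.residue(row.template_chain, row.template_seq)
        c_res = complex_.residue(row.complex_chain, row.complex_seq)
        if t_res is None or c_res is None:
            continue
        for name in _ALIGN_ATOM_PREFERENCE:
            ta, ca = t_res.atom(name), c_res.atom(name)
            if ta is not None and ca is not None:
                fixed.append(ta.coords)
                mobile.append(ca.coords)
                break
        else:
            # residues without a canonical anchor (e.g. envelope
            # pseudo-atoms) are matched on their first common atom name
            common = next((a.name for a in c_res.atoms
                           if t_res.atom(a.name) is not None), None)
            if common is not None:
                fixed.append(t_res.atom(common).coords)
                mobile.append(c_res.atom(common).coords)
    return np.array(fixed), np.array(mobile)


@dataclass
class TemplatedDimer:
    assembly: Structure
    copies: tuple[Structure, Structure]
    transforms_N: tuple[RigidTransform, RigidTransform]
    transforms_C: tuple[RigidTransform, RigidTransform]
    metrics: DimerMetrics
    clash_report: ClashReport


def build_topo6_templated_dimer(
    complex_: Structure,
    template: Structure,
    split: DomainSplit,
    mapping: list[MappingRow],
    protomer_chains: tuple[tuple[str, ...], tuple[str, ...]],
    criterion: ClashCriterion | None = None,
    reference_chain: str | None = None,
) -> TemplatedDimer:
    """Assemble a dimer by aligning each complex part onto a dimer template.

    For each template protomer (identified by its chains), the WH-side part
    and the Toprim-side part of a copy of the complex are independently
    superposed onto the protomer via the residue *mapping*; the DNA moves
    with the WH-side part.  Metrics are reported for protomer 1 (the two
    protomers of a symmetric template give identical numbers).
    """
    criterion = criterion or ClashCriterion()
    if not split.check_partition(complex_):
        raise ValueError("DomainSplit does not partition the complex")
    part_N = select(complex_, split.part_N)
    part_C = select(complex_, split.part_C)

    copies, tNs, tCs = [], [], []
    rmsds = []
    for p, chains in enumerate(protomer_chains):
        rows_p = [r for r in mapping if r.template_chain in chains]
        rows_N = [r for r in rows_p
                  if _row_in_part(complex_, r, split.part_N)]
        rows_C = [r for r in rows_p
                  if _row_in_part(complex_, r, split.part_C)]
        fN, mN = _mapped_coords(complex_, template, rows_N)
        fC, mC = _mapped_coords(complex_, template, rows_C)
        if len(fN) < 3 or len(fC) < 3:
            raise ValueError(
                f"protomer {p + 1}: mapping yields <3 atom pairs per part "
                f"({len(fN)} N-side, {len(fC)} C-side)")
        supN = kabsch(fN, mN)
        supC = kabsch(fC, mC)
        tNs.append(supN.transform)
        tCs.append(supC.transform)
        rmsds.append((supN.rmsd, supN.n_pairs, supC.rmsd, supC.n_pairs))
        suffix = "" if p == 0 else "2"
        copy = concat([part_N.transformed(supN.transform),
                       part_C.transformed(supC.transform)])
        if suffix:
            copy = copy.renamed_chains({c: c + suffix for c in copy.chain_ids})
        copies.append(copy)

    wh_rot, _ = rotation_angle(tNs[0] @ tCs[0].inverse())
    combined, pp, pd = _split_clashes(copies[0], copies[1], criterion)
    dna1 = select(copies[0], Sel(polymer=("nucleotide",)))
    dna2 = select(copies[1], Sel(polymer=("nucleotide",)))
    if dna1.n_atoms and dna2.n_atoms:
        angle, offset, end_sep = dimer_dna_geometry(dna1, dna2,
                                                    reference_chain)
    else:
        angle = offset = end_sep = float("nan")
    r1 = rmsds[0]
    metrics = DimerMetrics(
        rmsd_N=r1[0], n_pairs_N=r1[1], rmsd_C=r1[2], n_pairs_C=r1[3],
        wh_rotation=wh_rot, inter_dna_angle=angle, axis_offset=offset,
        end_separation=end_sep, n_clashes=combined.n_clashes)
    assembly = concat(copies, id="templated-dimer")
    return TemplatedDimer(assembly, (copies[0], copies[1]),
                          (tNs[0], tNs[1]), (tCs[0], tCs[1]),
                          metrics, combined)


def _row_in_part(complex_: Structure, row: MappingRow, part: Selection) -> bool:
    res = complex_.residue(row.complex_chain, row.complex_seq)
    return res is not None and any(part.matches_atom(res, a) for a in res.atoms)


# ---------------------------------------------------------------------------
# DNA geometry of a dimer
# ---------------------------------------------------------------------------

def _end_atoms(dna: Structure, reference_chain: str | None):
    """(5'-phosphate of the innermost traced overhang nt, 3'-terminal atom).

    The 5' position is the P of the 5'-most reference-strand residue that
    has one (the 5'-terminal residue itself carries no phosphate); C5'/C1'
    are fallbacks.  The 3' position is the O3' (fallback C1') of the
    non-reference strand's 3'-terminal residue.
    """
    nts = [r for r in dna.residues if r.polymer_class == "nucleotide"]
    if reference_chain is None:
        reference_chain = nts[0].chain_id
    ref = [r for r in nts if r.chain_id == reference_chain]
    other = [r for r in nts if r.chain_id != reference_chain]
    if not ref or not other:
        raise ValueError("dimer DNA copy lacks two strands")
    five = next((r.atom("P").coords for r in ref if r.atom("P") is not None),
                None)
    if five is None:
        for name in ("C5'", "C1'"):
            a = ref[0].atom(name)
            if a is not None:
                five = a.coords
                break
    last = other[-1]       # 3'-terminal residue of the recessed strand
    three = None
    for name in ("O3'", "C1'"):
        a = last.atom(name)
        if a is not None:
            three = a.coords
            break
    if five is None or three is None:
        raise ValueError("cannot locate 5'/3' end atoms")
    return five, three


def dimer_dna_geometry(dna1: Structure, dna2: Structure,
                       reference_chain: str | None = None
                       ) -> tuple[float, float, float]:
    """(V-angle deg, axis offset A, 5'-to-3' end separation A) of two DNA
    copies in a dimer.

    Each axis is oriented 5'->3' along its overhang-bearing reference
    strand, i.e. away from the junction, so a straight through path scores
    180 degrees.  End separation pairs copy 1's 5' phosphate with copy 2's
    recessed 3' end (the two ends that would be joined in the intact
    strand); the two pairings are symmetric and averaged.
    """
    ref1 = _resolve_reference(dna1, reference_chain)
    ref2 = _resolve_reference(dna2, reference_chain)
    ax1 = fit_helical_axis(dna1, ref1)
    ax2 = fit_helical_axis(dna2, ref2)
    angle = interaxis_angle(ax1, ax2)
    offset = axis_offset(ax1, ax2)
    five1, three1 = _end_atoms(dna1, ref1)
    five2, three2 = _end_atoms(dna2, ref2)
    sep = 0.5 * (np.linalg.norm(five1 - three2) + np.linalg.norm(five2 - three1))
    return float(angle), float(offset), float(sep)


def _resolve_reference(dna: Structure, reference_chain: str | None) -> str | None:
    """Map a reference-chain name onto a copy whose chains may carry a
    renaming suffix (copy 2 of an assembly appends ``2``)."""
    if reference_chain is None:
        return None
    chains = set(dna.chain_ids)
    if reference_chain in chains:
        return reference_chain
    if reference_chain + "2" in chains:
        return reference_chain + "2"
    return None
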