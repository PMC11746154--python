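"""Double-end docking of DNA-bound complexes and the clash-vs-length scan.

Two rigid copies of a DNA-end-bound complex are docked on opposite ends of
an idealized B-form rail by superposing the first few fully paired base
pairs of each copy's bound DNA onto the corresponding rail base-pair
positions.  The copy at the far end is anchored in the opposite strand
sense, so the two complexes face each other the way two break-flanking
complexes would.  Sweeping the rail length L and counting inter-complex
steric clashes reproduces the geometry that sets the minimum spacing of
adjacent double-strand breaks: shortening the rail by one base pair rotates
the far copy by one helical twist and brings it one rise closer.

Clash counting is between the two protein moieties only by default (each
copy's bound DNA and the rail are excluded), configurable via
``include_dna``.

Co-orientation: two placements related by an integral number of helical
turns (relative rotation about the rail axis within a tolerance, default
18 degrees = half a base-pair twist).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bdna import HelixParams, build_bform_duplex
from .geometry import RigidTransform, kabsch, paired_nucleotides
from .interfaces import ClashCriterion, ClashReport, count_clashes
from .structures import Residue, Sel, Structure, concat, select

__all__ = [
    "DockSpec",
    "DockedAssembly",
    "ScanResult",
    "dock_double_end",
    "clash_vs_length_scan",
    "min_cooriented_clashfree",
    "relative_rotation_about_rail",
]

RAIL_CHAINS = ("X", "Y")

#: atoms used for frame-matching a bound base pair onto the rail, in
#: preference order; P is skipped where absent (5' termini)
_ANCHOR_ATOMS = ("C1'", "P")


@dataclass
class DockSpec:
    """What to dock: the complex and how to anchor its bound DNA.

    ``n_anchor_bp`` fully paired base pairs at the overhang-proximal end of
    the bound duplex are frame-matched to the rail.  ``reference_chain``
    names the strand whose 5'->3' direction defines base-pair order
    (default: the first chain containing nucleotides, which for complexes
    bound at a 5'-overhang end is the overhang strand).
    """

    complex: Structure
    n_anchor_bp: int = 4
    reference_chain: str | None = None

    def anchor_pairs(self) -> list[tuple[Residue, Residue]]:
        pairs = paired_nucleotides(self.complex, self.reference_chain)
        if len(pairs) < max(3, self.n_anchor_bp):
            raise ValueError(
                f"anchor needs >= {max(3, self.n_anchor_bp)} paired bp, "
                f"found {len(pairs)}")
        return pairs[: self.n_anchor_bp]


def _residue_anchor_coords(res: Residue, names=_ANCHOR_ATOMS) -> dict[str, np.ndarray]:
    return {n: a.coords for n in names if (a := res.atom(n)) is not None}


def _pair_coords(complex_res: Residue, rail_res: Residue):
    """Matched (rail, complex) coordinate pairs for one residue mapping."""
    ca = _residue_anchor_coords(complex_res)
    cr = _residue_anchor_coords(rail_res)
    fixed, mobile = [], []
    for name in _ANCHOR_ATOMS:
        if name in ca and name in cr:
            fixed.append(cr[name])
            mobile.append(ca[name])
    return fixed, mobile


def _docking_transform(spec: DockSpec, rail: Structure, L: int,
                       flipped: bool) -> RigidTransform:
    """Kabsch fit of the complex's anchor bp onto rail bp frames.

    Unflipped: anchor bp k maps to rail bp k (reference strand along rail
    strand 1).  Flipped: anchor bp k maps to rail bp L-1-k with the
    reference strand along rail strand 2, i.e. the opposite strand sense.
    """
    fixed, mobile = [], []
    for k, (ref_res, par_res) in enumerate(spec.anchor_pairs()):
        if flipped:
            # rail strand-2 residue seq k+1 pairs bp L-1-k
            rail_ref = rail.residue(RAIL_CHAINS[1], k + 1)
            rail_par = rail.residue(RAIL_CHAINS[0], L - k)
        else:
            rail_ref = rail.residue(RAIL_CHAINS[0], k + 1)
            rail_par = rail.residue(RAIL_CHAINS[1], L - k)
        for c_res, r_res in ((ref_res, rail_ref), (par_res, rail_par)):
            f, m = _pair_coords(c_res, r_res)
            fixed.extend(f)
            mobile.extend(m)
    if len(fixed) < 3:
        raise ValueError("anchor pairing yielded fewer than 3 atom pairs")
    return kabsch(np.array(fixed), np.array(mobile)).transform


def relative_rotation_about_rail(t1: RigidTransform, t2: RigidTransform) -> float:
    """Azimuthal rotation (degrees, folded to [0, 180]) between two docked
    placements on a +z rail, after removing the end-to-end flip.

    For ideal docking ``t2 . t1^-1 = step^(L-1) . flip`` so the residual
    ``(t2 . t1^-1) . flip^-1`` is a pure rotation about z whose angle is
    the relative helical register of the two copies.
    """
    flip = RigidTransform.about_axis([1.0, 0.0, 0.0], 180.0)
    residual = (t2 @ t1.inverse()) @ flip.inverse()
    A = residual.rotation
    theta = np.degrees(np.arctan2(A[1, 0], A[0, 0]))
    theta = abs(theta) % 360.0
    return float(min(theta, 360.0 - theta))


@dataclass
class DockedAssembly:
    """Two docked copies plus the rail they were docked on."""

    assembly: Structure
    copy1: Structure
    copy2: Structure
    rail: Structure
    t1: RigidTransform
    t2: RigidTransform
    length: int

    @property
    def relative_rotation(self) -> float:
        return relative_rotation_about_rail(self.t1, self.t2)


def dock_double_end(spec: DockSpec, L: int,
                    params: HelixParams | None = None) -> DockedAssembly:
    """Place two copies of the complex on opposite ends of an L-bp rail."""
    params = params or HelixParams()
    if L < 2 * spec.n_anchor_bp:
        raise ValueError(
            f"rail of {L} bp too short for two {spec.n_anchor_bp}-bp anchors")
    rail = build_bform_duplex("A" * L, params, chain_ids=RAIL_CHAINS,
                              structure_id=f"rail-{L}")
    t1 = _docking_transform(spec, rail, L, flipped=False)
    t2 = _docking_transform(spec, rail, L, flipped=True)
    copy1 = spec.complex.transformed(t1)
    copy2 = spec.complex.transformed(t2).renamed_chains(
        {c: c + "2" for c in spec.complex.chain_ids})
    assembly = concat([copy1, copy2], id=f"double-end-{L}bp")
    return DockedAssembly(assembly, copy1, copy2, rail, t1, t2, L)


@dataclass(frozen=True)
class ScanResult:
    """One record of the clash-vs-length scan.

    ``center_to_center`` is the duplex length plus the two overhang
    nucleotides, i.e. the spacing measured between the centers of the two
    break overhangs.
    """

    length: int
    n_clashes: int
    relative_rotation: float
    co_oriented: bool
    center_to_center: int

    def __post_init__(self):
        assert self.center_to_center - self.length == 2


_NON_DNA = Sel(polymer=("protein", "ion", "other"))


def _clash_moiety(copy: Structure, include_dna: bool) -> Structure:
    return copy if include_dna else select(copy, _NON_DNA)


def clash_vs_length_scan(spec: DockSpec, lengths,
                         criterion: ClashCriterion | None = None,
                         params: HelixParams | None = None,
                         coorient_tol: float = 18.0,
                         include_dna: bool = False) -> list[ScanResult]:
    """Dock at every length in *lengths* and count inter-copy clashes.

    Clashes are counted between the two copies' protein moieties (plus ions
    and envelope pseudo-atoms); each copy's bound DNA and the rail are
    excluded unless ``include_dna`` is set.
    """
    params = params or HelixParams()
    criterion = criterion or ClashCriterion()
    results = []
    for L in lengths:
        docked = dock_double_end(spec, int(L), params)
        report = count_clashes(_clash_moiety(docked.copy1, include_dna),
                               _clash_moiety(docked.copy2, include_dna),
                               criterion)
        rot = docked.relative_rotation
        results.append(ScanResult(
            length=int(L),
            n_clashes=report.n_clashes,
            relative_rotation=rot,
            co_oriented=rot <= coorient_tol,
            center_to_center=int(L) + 2,
        ))
    return results


def min_cooriented_clashfree(scan: list[ScanResult],
                             max_clashes: int = 0) -> tuple[int | None, list[int]]:
    """Smallest co-oriented length with at most *max_clashes* clashes.

    Returns ``(min_length_or_None, all_qualifying_lengths_ascending)``; the
    ascending list exposes the helical periodicity of qualifying spacings.
    """
    qualifying = sorted(r.length for r in scan
                        if r.co_oriented and r.n_clashes <= max_clashes)
    return (qualifying[0] if qualifying else None), qualifying
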