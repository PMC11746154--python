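"""Download-free synthetic fixtures with analytically known geometry.

The toy complex emulates the one geometric fact the docking analyses rely
on: a DNA-end-bound complex is a rigid excluded volume attached to a duplex
with a two-nucleotide 5' overhang and a recessed 3' end.  The envelope is
either a hollow sphere of pseudo-atoms centered on the helix axis (for
which the duplex length at which two docked copies stop clashing has a
closed form) or a left-handed wrap of pseudo-atoms around the duplex
(emulating how the real complexes embrace the DNA).  Envelope pseudo-atoms
use element C, so the standard radii apply, and the residue name ``ENV``,
so they are excluded from protein classification but included in the
protein-moiety clash counts of the spacing analyses.

Every emitted "expected" number is an analytic consequence of the spec and
is re-derived by brute force in the test suite; nothing is fit to output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .bdna import HelixParams, build_bform_duplex
from .geometry import RigidTransform
from .interfaces import fibonacci_sphere
from .structures import Atom, Residue, Structure

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "make_toy_complex",
    "make_perturbed_pair",
    "sphere_clash_free_onset",
    "make_synthetic_dimer_template",
    "toy_domain_split",
]

_CARBON_VDW = 1.70


@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry of a synthetic DNA-end-bound complex.

    ``dna_length`` is the paired duplex length (bp); ``overhang`` 5'
    nucleotides extend the reference strand beyond the duplex.  The sphere
    envelope has radius ``radius`` (angstrom) centered on the helix axis
    ``center_bp`` base-pair steps above the first paired base pair; the
    wrap envelope is a left-handed helix of pseudo-atoms of winding radius
    ``radius``, axial extent ``pitch`` and total turning angle ``arc_deg``.
    """

    dna_length: int = 14
    overhang: int = 2
    envelope: str = "sphere"            # "sphere" | "wrap"
    radius: float = 25.0
    center_bp: float = 6.0
    pitch: float = 25.0                 # wrap only: axial extent, angstrom
    arc_deg: float = 540.0              # wrap only: total turn, degrees
    n_envelope_atoms: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("envelope radius must be positive")
        if self.dna_length < 4:
            raise ValueError("toy duplex needs >= 4 paired bp")
        if self.envelope not in ("sphere", "wrap"):
            raise ValueError(f"unknown envelope {self.envelope!r}")


@dataclass
class ToyComplex:
    structure: Structure
    spec: ToyComplexSpec
    truth: dict


def sphere_clash_free_onset(spec: ToyComplexSpec, params: HelixParams,
                            overlap_cutoff: float) -> int:
    """Smallest rail length L with zero envelope-envelope clashes.

    When two sphere-envelope toy complexes are docked on opposite ends of
    an L-bp rail, the envelope centers sit on the rail axis at heights
    ``h`` and ``(L-1)*rise - h`` with ``h = center_bp * rise``, so the
    center distance is ``D = (L-1)*rise - 2h``.  The closest pseudo-atom
    approach is ``D - 2R`` (pole atoms face each other on the axis), and a
    carbon-carbon pair clashes iff ``2*1.70 - (D - 2R) >= cutoff``.  The
    largest clashing L is therefore
    ``floor((2R + 3.40 - cutoff + 2h) / rise) + 1``.
    """
    h = spec.center_bp * params.rise
    reach = 2.0 * spec.radius + 2.0 * _CARBON_VDW - overlap_cutoff + 2.0 * h
    return int(np.floor(reach / params.rise)) + 2


def _sphere_atoms(spec: ToyComplexSpec, params: HelixParams) -> list[Atom]:
    center = np.array([0.0, 0.0,
                       (spec.overhang + spec.center_bp) * params.rise])
    # an axial chain of atoms (spacing <= 1 A, endpoints on the poles)
    # guarantees that two interpenetrating envelopes always clash and that
    # the minimum inter-envelope gap equals the center distance minus 2R
    m = max(3, int(np.ceil(2.0 * spec.radius)) + 1)
    chain = [center + np.array([0.0, 0.0, u])
             for u in np.linspace(-spec.radius, spec.radius, m)]
    surface = list(center + spec.radius * fibonacci_sphere(spec.n_envelope_atoms))
    return [Atom(f"C{i + 1}", "C", p)
            for i, p in enumerate(chain + surface)]


def _wrap_atoms(spec: ToyComplexSpec, params: HelixParams) -> list[Atom]:
    n = spec.n_envelope_atoms
    t = np.linspace(0.0, 1.0, n)
    # left-handed: angle decreases while z increases (DNA itself is
    # right-handed); the wrap starts at the 5'-overhang end, embracing the
    # overhang region the way the real complex's domains cap the break end
    ang = np.deg2rad(-spec.arc_deg * t)
    x = spec.radius * np.cos(ang)
    y = spec.radius * np.sin(ang)
    z = spec.pitch * t
    pts = [np.array([x[i], y[i], z[i]]) for i in range(n)]
    pts += _end_cap_points(spec.radius, z_cap=-2.0)
    return [Atom(f"C{i + 1}", "C", p) for i, p in enumerate(pts)]


def _end_cap_points(rmax: float, z_cap: float, spacing: float = 2.0) -> list:
    """A disc of pseudo-atoms capping the break end (all azimuths covered,
    so end-on collisions register regardless of helical register)."""
    pts = [np.array([0.0, 0.0, z_cap])]
    r = spacing
    while r <= rmax + 1e-9:
        m = max(6, int(np.ceil(2.0 * np.pi * r / spacing)))
        pts.extend(np.array([r * np.cos(2 * np.pi * k / m),
                             r * np.sin(2 * np.pi * k / m), z_cap])
                   for k in range(m))
        r += spacing
    return pts


def make_toy_complex(spec: ToyComplexSpec | None = None,
                     params: HelixParams | None = None) -> ToyComplex:
    """Build a toy DNA-end-bound complex plus its analytic truth record.

    The structure holds a duplex of ``dna_length`` paired bp whose
    reference strand (chain A) carries ``overhang`` unpaired 5'
    nucleotides (the partner strand's 3' end is recessed, as at a real
    two-nucleotide 5'-overhang break), plus the rigid envelope (chain E,
    residue ``ENV``).  ``truth`` records, for a grid of clash cutoffs, the
    smallest clash-free and smallest co-oriented clash-free rail lengths of
    the double-end docking analysis (sphere envelopes only; for wraps the
    onset has no closed form and the brute-force scan is the reference).
    """
    spec = spec or ToyComplexSpec()
    params = params or HelixParams()
    total = spec.overhang + spec.dna_length
    seq = _toy_sequence(total, spec.seed)
    duplex = build_bform_duplex(seq, params, chain_ids=("A", "B"),
                                structure_id="toy-complex")
    # strip the partner residues of the overhang base pairs: bp i pairs
    # strand-2 residue seq total - i, so bps 0..overhang-1 are the last
    # `overhang` residues of strand B (its 3'-terminal end)
    drop = {("B", total - i) for i in range(spec.overhang)}
    duplex.residues = [r for r in duplex.residues
                       if (r.chain_id, r.seq_id) not in drop]
    atoms = (_sphere_atoms(spec, params) if spec.envelope == "sphere"
             else _wrap_atoms(spec, params))
    # one residue per pseudo-atom so selections and residue-level mappings
    # can address the envelope at atom granularity
    duplex.residues.extend(
        Residue("E", i + 1, "ENV", [a]) for i, a in enumerate(atoms))

    truth: dict = {"n_envelope_atoms": len(atoms)}
    if spec.envelope == "sphere":
        for cutoff in (0.4, 0.6):
            onset = sphere_clash_free_onset(spec, params, cutoff)
            truth[f"first_clash_free_L_cutoff_{cutoff}"] = onset
            truth[f"min_cooriented_clash_free_L_cutoff_{cutoff}"] = (
                _min_cooriented_at_least(onset, params))
    return ToyComplex(duplex, spec, truth)


def _toy_sequence(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def _min_cooriented_at_least(lmin: int, params: HelixParams,
                             tol: float = 18.0) -> int:
    """Smallest L >= lmin whose docked copies are co-oriented.

    The relative helical register of the two copies is (L-1)*twist mod 360
    (folded to [0, 180]); co-oriented means within *tol*.
    """
    L = lmin
    while True:
        rot = ((L - 1) * params.twist) % 360.0
        if min(rot, 360.0 - rot) <= tol:
            return L
        L += 1


def make_perturbed_pair(base: Structure, sigma: float, seed: int,
                        confidence: float = 0.99
                        ) -> tuple[Structure, Structure, tuple[float, float]]:
    """A rigidly moved, Gaussian-perturbed copy of *base* with RMSD bounds.

    The second structure is *base* under a random rigid transform plus
    i.i.d. N(0, sigma^2) noise on every coordinate.  The returned bounds
    are the central *confidence* interval of the optimally superposed RMSD:
    the fitted residual sum behaves as ``sigma^2 * chi2(3n - 6)`` to first
    order (the rigid fit absorbs six degrees of freedom), so the bounds are
    ``sigma * sqrt(chi2_q / n)`` at the interval quantiles.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-25.0, 25.0, size=3)
    t = RigidTransform(rot, trans)
    moved = base.transformed(t)
    n = moved.n_atoms
    for _, a in moved.iter_atoms():
        a.coords = a.coords + rng.normal(0.0, sigma, size=3)
    if sigma == 0 or n <= 2:
        bounds = (0.0, 0.0)
    else:
        k = 3 * n - 6
        alpha = (1.0 - confidence) / 2.0
        lo = sigma * np.sqrt(stats.chi2.ppf(alpha, k) / n)
        hi = sigma * np.sqrt(stats.chi2.ppf(1.0 - alpha, k) / n)
        bounds = (float(lo), float(hi))
    return base.copy(), moved, bounds


# ---------------------------------------------------------------------------
# Synthetic dimer template (stand-in for a real two-protomer template)
# ---------------------------------------------------------------------------

def toy_domain_split():
    """Domain split of a toy complex: DNA is the WH-side rigid body, the
    envelope the Toprim-side one."""
    from .dimer import DomainSplit
    from .structures import Sel

    return DomainSplit(part_N=Sel(chain_ids=("A", "B")),
                       part_C=Sel(chain_ids=("E",)),
                       boundary=(0, 1))


def make_synthetic_dimer_template(
    toy: ToyComplex,
    v_angle_deg: float = 150.0,
    axis_offset: float = 5.0,
    wh_rotation_deg: float = 45.0,
    junction_z: float = -6.76,
):
    """Construct a SYNTHETIC two-protomer dimer template from a toy complex.

    This is a geometric stand-in for a real two-protomer topoisomerase
    dimer: each "protomer" is a copy of the toy complex whose two rigid
    bodies (DNA-side and envelope-side) are placed by known transforms, so
    template-guided dimer assembly against it must recover those
    transforms exactly.  By construction:

    * protomer 1 keeps the DNA-side body at the identity and rotates the
      envelope-side body by ``wh_rotation_deg`` about the helix axis, so
      the recovered WH-vs-Toprim rotation equals ``wh_rotation_deg``;
    * protomer 2's DNA axis makes a ``v_angle_deg`` path angle with
      protomer 1's (both oriented away from the junction at
      ``(0, 0, junction_z)``) and is displaced by ``axis_offset`` along
      the common normal of the two axes.

    Returns ``(template, mapping, protomer_chains, split, transforms)``
    where *transforms* is ``((t_N1, t_C1), (t_N2, t_C2))``.
    """
    from .dimer import MappingRow
    from .structures import concat, select

    split = toy_domain_split()
    cx = toy.structure
    j = np.array([0.0, 0.0, junction_z])
    t_n1 = RigidTransform.identity()
    t_c1 = RigidTransform.about_axis([0.0, 0.0, 1.0], wh_rotation_deg,
                                     point=j)
    rot2 = RigidTransform.about_axis([1.0, 0.0, 0.0], 180.0 - v_angle_deg + 180.0,
                                     point=j)
    shift = RigidTransform.translation_of([axis_offset, 0.0, 0.0])
    t_n2 = shift @ rot2
    t_c2 = t_n2 @ t_c1
    transforms = ((t_n1, t_c1), (t_n2, t_c2))

    part_n = select(cx, split.part_N)
    part_c = select(cx, split.part_C)
    protomer_chains = []
    pieces = []
    mapping = []
    for p, (tn, tc) in enumerate(transforms, start=1):
        ren = {c: f"T{c}{p}" for c in cx.chain_ids}
        pieces.append(concat([part_n.transformed(tn),
                              part_c.transformed(tc)]).renamed_chains(ren))
        protomer_chains.append(tuple(ren[c] for c in cx.chain_ids))
        for r in cx.residues:
            mapping.append(MappingRow(r.chain_id, r.seq_id,
                                      ren[r.chain_id], r.seq_id))
    template = concat(pieces, id="synthetic-dimer-template")
    return template, mapping, tuple(protomer_chains), split, transforms
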