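"""Idealized B-form DNA duplexes and per-base-pair rigid frames.

The duplex is a helical repeat of a single coarse base-pair template: per
nucleotide a phosphate (P, absent at each strand's 5' terminus), the sugar
anchor C1', the glycosidic nitrogen (N9 for purines, N1 for pyrimidines)
and two ring-carbon anchors (C2, C4).  This is enough to define docking
frames, helical axes and backbone spacing; it is *not* an all-atom fiber
model and is never used for clash counting (the real complexes' atoms are).

Frame convention: the helix axis is +z starting from the fixed end; base
pair ``i`` sits at ``frame(i) = step**i`` with ``step`` = rotation by the
helical twist about +z composed with a rise translation along +z.  The
second strand is generated from the first by the base-pair dyad (a 180
degree rotation about the local x axis), which makes the strands
antiparallel by construction.  Default parameters are generic B-form values
(36 degrees/bp, i.e. 10 bp/turn, and 3.38 angstrom/bp); both are
configurable and the spacing analyses are reported at 34.3 degrees
(10.5 bp/turn) as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import IDEAL_PAIR_ANCHORS, RigidTransform
from .structures import Atom, Residue, Structure

__all__ = [
    "HelixParams",
    "BaseFrame",
    "helix_step",
    "helical_frame_at",
    "base_pair_flip",
    "build_bform_duplex",
    "strand_sequences",
    "adjacent_p_distance",
    "BP_TEMPLATE_STRAND1",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PURINES = {"A", "G"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class HelixParams:
    """Helical twist (degrees per bp step) and rise (angstrom per bp step)."""

    twist: float = 36.0
    rise: float = 3.38

    def __post_init__(self) -> None:
        if not (20.0 <= self.twist <= 45.0):
            raise ValueError(f"twist {self.twist} outside guard rails [20, 45] deg/bp")
        if not (2.5 <= self.rise <= 4.5):
            raise ValueError(f"rise {self.rise} outside guard rails [2.5, 4.5] A/bp")

    @property
    def bp_per_turn(self) -> float:
        return 360.0 / self.twist


#: Coarse nucleotide template, strand 1, in the local base-pair frame
#: (x = dyad axis, z = helix axis).  Values approximate canonical B-form
#: geometry: C1'-C1' across the pair = 10.80 A, phosphate radius ~9 A.
#: The template is laid out so the C1'-C1' midpoint of every pair falls
#: exactly on the helix axis, which makes the midpoint principal-component
#: axis fit exact on built duplexes.  The phosphate sits half a step toward
#: the residue's 5' side (-z for strand 1); strand 2 positions follow by
#: the dyad flip (x, -y, -z).
BP_TEMPLATE_STRAND1: dict[str, np.ndarray] = {
    "P": np.array([1.76, 8.88, -1.69]),
    "C1'": IDEAL_PAIR_ANCHORS["C1_ref"],
    "N": IDEAL_PAIR_ANCHORS["N_ref"],
    "C2": np.array([1.77, 3.80, 0.00]),
    "C4": np.array([3.07, 2.90, 0.00]),
}


def helix_step(params: HelixParams) -> RigidTransform:
    """The generator: twist about +z then rise along +z."""
    rot = RigidTransform.about_axis([0.0, 0.0, 1.0], params.twist)
    return RigidTransform(rot.rotation, np.array([0.0, 0.0, params.rise]))


def helical_frame_at(params: HelixParams, i: int,
                     length: int | None = None) -> RigidTransform:
    """Frame placing the base-pair template at step *i* (``step**i``).

    If *length* is given, *i* must satisfy ``0 <= i < length``.
    """
    if length is not None and not (0 <= i < length):
        raise IndexError(f"bp index {i} out of range for length {length}")
    # closed form, exactly equal to step**i
    rot = RigidTransform.about_axis([0.0, 0.0, 1.0], params.twist * i)
    return RigidTransform(rot.rotation, np.array([0.0, 0.0, params.rise * i]))


@dataclass(frozen=True)
class BaseFrame:
    """Base-pair index plus the rigid frame placing the template there."""

    index: int
    transform: RigidTransform


#: 180 degree rotation about the base-pair dyad (local x): maps strand-1
#: template positions to strand-2 positions.
def base_pair_flip() -> RigidTransform:
    return RigidTransform.about_axis([1.0, 0.0, 0.0], 180.0)


def _nucleotide_atoms(base: str, frame: RigidTransform,
                      flip: bool, with_p: bool) -> list[Atom]:
    F = frame @ base_pair_flip() if flip else frame
    atoms = []
    for name, local in BP_TEMPLATE_STRAND1.items():
        if name == "P" and not with_p:
            continue
        label = name
        if name == "N":
            label = "N9" if base in _PURINES else "N1"
        el = "P" if name == "P" else ("N" if name == "N" else "C")
        atoms.append(Atom(label, el, F.apply(local)))
    return atoms


def build_bform_duplex(sequence: str,
                       params: HelixParams | None = None,
                       chain_ids: tuple[str, str] = ("A", "B"),
                       structure_id: str = "bdna") -> Structure:
    """Build an idealized blunt B-form duplex for *sequence*.

    Strand 1 (``chain_ids[0]``) carries *sequence* 5'->3' with base pair 0
    (the 5' terminus) at the fixed end, ascending +z; strand 2 is its
    reverse complement running antiparallel.  Residues are numbered 1-based
    along each strand in its own 5'->3' order.  Each strand's 5'-terminal
    residue has no phosphate.
    """
    params = params or HelixParams()
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bp")
    for pos, b in enumerate(seq):
        if b not in _COMPLEMENT:
            raise ValueError(f"invalid base {b!r} at position {pos + 1}")
    L = len(seq)
    out = Structure(id=structure_id)
    # strand 1: residue s (1-based) at bp s-1
    for s, base in enumerate(seq, start=1):
        frame = helical_frame_at(params, s - 1)
        atoms = _nucleotide_atoms(base, frame, flip=False, with_p=(s > 1))
        out.residues.append(Residue(chain_ids[0], s, "D" + base, atoms))
    # strand 2: residue k (1-based from its own 5' end) pairs bp L-k
    rc = reverse_complement(seq)
    for k, base in enumerate(rc, start=1):
        frame = helical_frame_at(params, L - k)
        atoms = _nucleotide_atoms(base, frame, flip=True, with_p=(k > 1))
        out.residues.append(Residue(chain_ids[1], k, "D" + base, atoms))
    return out


def strand_sequences(duplex: Structure) -> dict[str, str]:
    """Per-chain base sequence, 5'->3' (residues in stored order)."""
    seqs: dict[str, str] = {}
    for r in duplex.residues:
        if r.polymer_class != "nucleotide":
            continue
        seqs[r.chain_id] = seqs.get(r.chain_id, "") + r.name.lstrip("D")
    return seqs


def adjacent_p_distance(params: HelixParams) -> float:
    """Closed-form intra-strand P-P distance for one helical step.

    Successive phosphates of a strand are related by the helix step, so the
    distance is the chord of a helix of radius ``|P_xy|``:
    ``sqrt(2 r^2 (1 - cos twist) + rise^2)``.
    """
    p = BP_TEMPLATE_STRAND1["P"]
    r2 = float(p[0] ** 2 + p[1] ** 2)
    tw = np.deg2rad(params.twist)
    return float(np.sqrt(2.0 * r2 * (1.0 - np.cos(tw)) + params.rise ** 2))
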