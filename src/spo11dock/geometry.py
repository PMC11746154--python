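"""Rigid-body superposition, transforms, axis fitting and distance metrics.

Superposition is the closed-form least-squares (Kabsch) fit; the reflection
branch of the SVD is always folded back to a proper rotation.  Helical axes
of duplex fragments are fit by a principal-component line through base-pair
midpoints, which is robust and deterministic for the short (<= 25 bp)
fragments handled here.

Angle conventions: ``rotation_angle`` returns the geodesic rotation angle in
[0, 180] degrees from the trace formula.  ``interaxis_angle`` is the angle
between two *oriented* axis directions, so two duplexes whose axes are
oriented away from a common junction score 180 degrees when the DNA path is
straight -- the convention used for V-shape bend angles throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Sel, Selection, Structure, select

__all__ = [
    "RigidTransform",
    "AxisLine",
    "SuperpositionResult",
    "kabsch",
    "superpose_structures",
    "rotation_angle",
    "fit_helical_axis",
    "paired_nucleotides",
    "interaxis_angle",
    "axis_offset",
    "atom_distance",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation: ``x -> R @ x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {np.linalg.det(R):.6f} != +1")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation columns are not orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(cls, axis: np.ndarray, angle_deg: float,
                   point: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by *angle_deg* about *axis* through *point* (or origin)."""
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        if point is None:
            return cls(R, np.zeros(3))
        p = np.asarray(point, dtype=float)
        return cls(R, p - R @ p)

    @classmethod
    def translation_of(cls, t: np.ndarray) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies *other* first, then *self*."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def power(self, n: int) -> "RigidTransform":
        out = RigidTransform.identity()
        step = self if n >= 0 else self.inverse()
        for _ in range(abs(n)):
            out = step @ out
        return out


def rotation_angle(t: RigidTransform) -> tuple[float, np.ndarray]:
    """Rotation angle (degrees, in [0, 180]) and unit axis of *t*.

    The axis of a near-identity rotation is ill-defined; ``(0, +z)`` is
    returned in that case.
    """
    R = t.rotation
    cos_th = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_th))
    w, v = np.linalg.eig(R)
    k = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, k])
    nrm = np.linalg.norm(axis)
    if angle < 1e-8 or nrm == 0:
        return float(angle), np.array([0.0, 0.0, 1.0])
    axis = axis / nrm
    # orient the axis so the rotation about it is by +angle (right-handed)
    sin_part = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.dot(sin_part, axis) < 0:
        axis = -axis
    return float(angle), axis


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid fit of *mobile* onto *fixed*."""

    transform: RigidTransform
    rmsd: float
    n_pairs: int


def kabsch(fixed: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of *mobile* onto *fixed*.

    Returns the transform minimizing the RMSD over all proper rigid
    transforms (reflections are excluded).  Requires >= 3 point pairs.
    """
    P = np.asarray(fixed, dtype=float)
    Q = np.asarray(mobile, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point counts differ: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need >= 3 paired 3D points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    transform = RigidTransform(R, t)
    diff = transform.apply(Q) - P
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(transform, rmsd, P.shape[0])


def _ca_pairs(fixed: Structure, mobile: Structure) -> tuple[np.ndarray, np.ndarray, int]:
    fixed_ca = {(r.chain_id, r.seq_id): a.coords
                for r, a in fixed.iter_atoms()
                if r.polymer_class == "protein" and a.name == "CA"}
    P, Q = [], []
    for r, a in mobile.iter_atoms():
        if r.polymer_class == "protein" and a.name == "CA":
            key = (r.chain_id, r.seq_id)
            if key in fixed_ca:
                P.append(fixed_ca[key])
                Q.append(a.coords)
    return np.array(P), np.array(Q), len(P)


def superpose_structures(
    fixed: Structure,
    mobile: Structure,
    pairing: str = "shared-ca",
    fixed_sel: Selection | None = None,
    mobile_sel: Selection | None = None,
) -> SuperpositionResult:
    """Superpose *mobile* onto *fixed*.

    ``pairing='shared-ca'`` (default) matches protein C-alpha atoms by
    (chain_id, seq_id) -- DNA is excluded, which is the right default when
    the two structures carry different nucleic-acid ligands.
    ``pairing='sequential'`` pairs the atoms of ``fixed_sel`` / ``mobile_sel``
    sub-structures in order (counts must agree).
    """
    if pairing == "shared-ca":
        f = fixed if fixed_sel is None else select(fixed, fixed_sel)
        m = mobile if mobile_sel is None else select(mobile, mobile_sel)
        P, Q, n = _ca_pairs(f, m)
        if n < 3:
            raise ValueError(
                "fewer than 3 shared C-alpha atoms between chains "
                f"{f.chain_ids} and {m.chain_ids}")
        return kabsch(P, Q)
    if pairing == "sequential":
        f = fixed if fixed_sel is None else select(fixed, fixed_sel)
        m = mobile if mobile_sel is None else select(mobile, mobile_sel)
        return kabsch(f.coords(), m.coords())
    raise ValueError(f"unknown pairing {pairing!r}")


# ---------------------------------------------------------------------------
# Helical axes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisLine:
    """An oriented line: a point on it and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction is zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)


#: Canonical paired-anchor geometry of one B-form base pair: C1' and the
#: glycosidic nitrogen of each strand, in the base-pair frame (helix axis
#: through the origin along z, dyad along x).  Shared with the duplex
#: builder; also the reference configuration against which candidate base
#: pairs are scored.
IDEAL_PAIR_ANCHORS = {
    "C1_ref": np.array([0.00, 5.40, 0.00]),
    "N_ref": np.array([1.00, 4.96, 0.00]),
    "C2_ref": np.array([1.77, 3.80, 0.00]),
    "C1_par": np.array([0.00, -5.40, 0.00]),   # dyad flip (x, -y, -z)
    "N_par": np.array([1.00, -4.96, 0.00]),
    "C2_par": np.array([1.77, -3.80, 0.00]),
}


def _glycosidic_n(res: Residue):
    for name in ("N9", "N1"):
        a = res.atom(name)
        if a is not None:
            return a
    return None


def _pair_fit_rmsd(ref: Residue, par: Residue) -> float:
    """RMSD of the four pair anchors against the canonical configuration.

    True Watson-Crick partners fit the canonical pair geometry closely;
    stacked or diagonal neighbours are off by a helical step and fit badly,
    so this score separates real pairs robustly where raw C1'-C1' distance
    does not.
    """
    fixed, mobile = [], []
    for res, side in ((ref, "ref"), (par, "par")):
        for key, atom in (("C1_", res.atom("C1'")), ("N_", _glycosidic_n(res)),
                          ("C2_", res.atom("C2"))):
            if atom is None:
                if key == "C2_":        # C2 is optional extra leverage
                    continue
                return np.inf
            fixed.append(IDEAL_PAIR_ANCHORS[key + side])
            mobile.append(atom.coords)
    if len(fixed) < 4:
        return np.inf
    return kabsch(np.array(fixed), np.array(mobile)).rmsd


def paired_nucleotides(duplex: Structure,
                       reference_chain: str | None = None,
                       max_c1_dist: float = 12.5,
                       max_pair_rmsd: float = 1.5):
    """Identify Watson-Crick-paired nucleotides geometrically.

    Candidates within *max_c1_dist* of each other (C1'-C1') are scored by
    rigid-fit RMSD against the canonical pair-anchor geometry; each
    reference residue takes its best-fitting partner below *max_pair_rmsd*
    and partners are used at most once (greedy, best score first).
    Returns (reference residue, partner residue) pairs ordered 5'->3'
    along the reference strand (the first chain containing nucleotides
    unless given).  Overhangs and single-stranded regions fall out
    naturally: they have no partner that fits the pair geometry.
    """
    nts = [r for r in duplex.residues if r.polymer_class == "nucleotide"]
    if not nts:
        return []
    if reference_chain is None:
        reference_chain = nts[0].chain_id
    ref = [r for r in nts if r.chain_id == reference_chain]
    others = [r for r in nts if r.chain_id != reference_chain]
    scored = []
    for i, r in enumerate(ref):
        c1 = r.atom("C1'")
        if c1 is None:
            continue
        for o in others:
            oc1 = o.atom("C1'")
            if oc1 is None:
                continue
            if float(np.linalg.norm(c1.coords - oc1.coords)) > max_c1_dist:
                continue
            score = _pair_fit_rmsd(r, o)
            if score <= max_pair_rmsd:
                scored.append((score, i, r, o))
    scored.sort(key=lambda t: t[0])
    taken_ref: set[int] = set()
    taken_par: set[int] = set()
    chosen: list[tuple[int, Residue, Residue]] = []
    for score, i, r, o in scored:
        if i in taken_ref or id(o) in taken_par:
            continue
        taken_ref.add(i)
        taken_par.add(id(o))
        chosen.append((i, r, o))
    chosen.sort(key=lambda t: t[0])
    return [(r, o) for _, r, o in chosen]


def fit_helical_axis(duplex: Structure,
                     reference_chain: str | None = None) -> AxisLine:
    """Fit a straight helical axis through base-pair C1'-C1' midpoints.

    The line is the first principal component of the midpoints; the
    direction is oriented 5'->3' along the reference strand.
    """
    pairs = paired_nucleotides(duplex, reference_chain)
    if len(pairs) < 4:
        raise ValueError(
            f"need >= 4 paired base pairs to fit an axis, found {len(pairs)}")
    mids = np.array([(r.atom("C1'").coords + o.atom("C1'").coords) / 2.0
                     for r, o in pairs])
    center = mids.mean(axis=0)
    _, _, Vt = np.linalg.svd(mids - center)
    d = Vt[0]
    if np.dot(mids[-1] - mids[0], d) < 0:
        d = -d
    return AxisLine(center, d)


def interaxis_angle(a: AxisLine, b: AxisLine) -> float:
    """Angle (degrees, [0, 180]) between the oriented directions of two axes."""
    c = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def axis_offset(a: AxisLine, b: AxisLine) -> float:
    """Minimal distance (angstrom) between two axis lines.

    For (near-)parallel lines the perpendicular distance between them is
    returned.
    """
    n = np.cross(a.direction, b.direction)
    dp = b.point - a.point
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        perp = dp - np.dot(dp, a.direction) * a.direction
        return float(np.linalg.norm(perp))
    return float(abs(np.dot(dp, n / nn)))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def atom_distance(s: Structure, sel_a: Selection, sel_b: Selection,
                  mode: str = "min") -> float:
    """Distance between two selections of *s*.

    ``mode='min'``: minimal heavy-atom distance between the selections.
    ``mode='ca-ca'``: distance between the single C-alpha atom of each
    selection (each must resolve to exactly one residue).
    """
    a = select(s, sel_a).without_hydrogens()
    b = select(s, sel_b).without_hydrogens()
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("empty selection in atom_distance")
    if mode == "min":
        from scipy.spatial import cKDTree

        tree = cKDTree(b.coords())
        d, _ = tree.query(a.coords(), k=1)
        return float(np.min(d))
    if mode == "ca-ca":
        for part, label in ((a, "A"), (b, "B")):
            if part.n_residues != 1:
                raise ValueError(
                    f"ca-ca mode needs single-residue selections; selection "
                    f"{label} has {part.n_residues} residues")
        ca_a = a.residues[0].atom("CA")
        ca_b = b.residues[0].atom("CA")
        if ca_a is None or ca_b is None:
            raise ValueError("ca-ca mode: C-alpha atom missing")
        return float(np.linalg.norm(ca_a.coords - ca_b.coords))
    raise ValueError(f"unknown mode {mode!r}")
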