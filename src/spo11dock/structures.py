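"""Atom-level structure container and mmCIF/PDB input/output.

The data model is a deliberately small hierarchy (Structure -> Residue ->
Atom) carrying author numbering, element symbols and coordinates in
angstroms.  Parsing and serialization of the crystallographic formats are
delegated to :mod:`gemmi`; everything downstream of this module works with
plain numpy coordinates.

Only heavy atoms matter for the analyses in this package: cryo-EM models of
the complexes studied here carry no hydrogens, and all distance criteria are
defined on heavy atoms.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Selection",
    "Sel",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "vdw_radius",
    "read_structure",
    "write_structure",
    "select",
    "concat",
    "EmptyStructureError",
    "FormatError",
]

#: Bondi-like van der Waals radii (angstrom) keyed by element symbol.
#: Hydrogens are absent from the models this package analyses and are
#: ignored throughout; unlisted elements fall back to the carbon radius.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "MG": 1.73,
}
DEFAULT_VDW_RADIUS = 1.70

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
NUCLEOTIDE_RESIDUES = {
    "DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "T", "U", "I",
}
ION_RESIDUES = {"MG", "ZN", "MN", "NA", "K", "CA", "CL", "FE", "CU", "NI"}


class FormatError(ValueError):
    """A structure file could not be parsed under the named standard."""


class EmptyStructureError(ValueError):
    """A parsed or supplied structure contains no atoms."""


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    """Van der Waals radius for *element*, falling back to carbon."""
    tab = VDW_RADII if table is None else table
    return tab.get(element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class Atom:
    """A single heavy atom: label, element, position (angstrom)."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element symbol is empty")

    @property
    def radius(self) -> float:
        return vdw_radius(self.element)

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(),
                    self.occupancy, self.is_hetero)


@dataclass
class Residue:
    """One residue, identified by (chain_id, author seq_id)."""

    chain_id: str
    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def polymer_class(self) -> str:
        """Classify as ``protein``, ``nucleotide``, ``ion`` or ``other``."""
        n = self.name.upper()
        if n in PROTEIN_RESIDUES:
            return "protein"
        if n in NUCLEOTIDE_RESIDUES:
            return "nucleotide"
        if n in ION_RESIDUES:
            return "ion"
        return "other"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_id, self.name,
                       [a.copy() for a in self.atoms])


@dataclass
class Structure:
    """An ordered collection of residues grouped into chains."""

    id: str = ""
    residues: list[Residue] = field(default_factory=list)
    source: str = ""

    # -- basic queries -------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str) -> "Structure":
        return Structure(self.id, [r for r in self.residues if r.chain_id == chain_id],
                         self.source)

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (N, 3) array (empty -> (0, 3))."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.coords for _, a in self.iter_atoms()])

    def radii(self, table: dict[str, float] | None = None) -> np.ndarray:
        return np.array([vdw_radius(a.element, table) for _, a in self.iter_atoms()])

    def elements(self) -> list[str]:
        return [a.element for _, a in self.iter_atoms()]

    def residue(self, chain_id: str, seq_id: int) -> Residue | None:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_id == seq_id:
                return r
        return None

    def copy(self) -> "Structure":
        return Structure(self.id, [r.copy() for r in self.residues], self.source)

    # -- geometry ------------------------------------------------------
    def transformed(self, transform) -> "Structure":
        """Return a copy with every coordinate mapped through *transform*.

        *transform* is a :class:`spo11dock.geometry.RigidTransform` (anything
        exposing ``apply``).
        """
        out = self.copy()
        for _, a in out.iter_atoms():
            a.coords = transform.apply(a.coords)
        return out

    def renamed_chains(self, mapping: dict[str, str]) -> "Structure":
        out = self.copy()
        for r in out.residues:
            r.chain_id = mapping.get(r.chain_id, r.chain_id)
        return out

    def without_hydrogens(self) -> "Structure":
        out = Structure(self.id, [], self.source)
        for r in self.residues:
            atoms = [a.copy() for a in r.atoms if a.element.upper() not in ("H", "D")]
            if atoms:
                out.residues.append(Residue(r.chain_id, r.seq_id, r.name, atoms))
        return out


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

class Selection:
    """Declarative, composable filter over residues and atoms.

    Combine with ``&`` (AND), ``|`` (OR) and ``~`` (NOT).  Selecting with a
    selection that matches nothing yields an empty Structure; referencing a
    chain that does not exist is not an error (a warning is logged).
    """

    def matches_residue(self, res: Residue) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def matches_atom(self, res: Residue, atom: Atom) -> bool:  # pragma: no cover
        raise NotImplementedError

    def __and__(self, other: "Selection") -> "Selection":
        return _And(self, other)

    def __or__(self, other: "Selection") -> "Selection":
        return _Or(self, other)

    def __invert__(self) -> "Selection":
        return _Not(self)


@dataclass(frozen=True)
class Sel(Selection):
    """Field-based selection; every unset field matches everything.

    ``seq_range`` is an inclusive (low, high) pair over author numbering;
    either bound may be ``None``.
    """

    chain_ids: tuple[str, ...] | None = None
    seq_range: tuple[int | None, int | None] | None = None
    residue_names: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None
    polymer: tuple[str, ...] | None = None

    def matches_residue(self, res: Residue) -> bool:
        if self.chain_ids is not None and res.chain_id not in self.chain_ids:
            return False
        if self.seq_range is not None:
            lo, hi = self.seq_range
            if lo is not None and res.seq_id < lo:
                return False
            if hi is not None and res.seq_id > hi:
                return False
        if self.residue_names is not None and res.name.upper() not in tuple(
                n.upper() for n in self.residue_names):
            return False
        if self.polymer is not None and res.polymer_class not in self.polymer:
            return False
        return True

    def matches_atom(self, res: Residue, atom: Atom) -> bool:
        if not self.matches_residue(res):
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True


class _And(Selection):
    def __init__(self, a: Selection, b: Selection):
        self.a, self.b = a, b

    def matches_residue(self, res: Residue) -> bool:
        return self.a.matches_residue(res) and self.b.matches_residue(res)

    def matches_atom(self, res: Residue, atom: Atom) -> bool:
        return self.a.matches_atom(res, atom) and self.b.matches_atom(res, atom)


class _Or(Selection):
    def __init__(self, a: Selection, b: Selection):
        self.a, self.b = a, b

    def matches_residue(self, res: Residue) -> bool:
        return self.a.matches_residue(res) or self.b.matches_residue(res)

    def matches_atom(self, res: Residue, atom: Atom) -> bool:
        return self.a.matches_atom(res, atom) or self.b.matches_atom(res, atom)


class _Not(Selection):
    def __init__(self, a: Selection):
        self.a = a

    def matches_residue(self, res: Residue) -> bool:
        # residue-level NOT is atom-driven: a residue stays if any atom passes
        return True

    def matches_atom(self, res: Residue, atom: Atom) -> bool:
        return not self.a.matches_atom(res, atom)


def select(s: Structure, sel: Selection) -> Structure:
    """Return the sub-structure of atoms matched by *sel*.

    Chain and residue identity is preserved; the original is untouched.
    """
    if isinstance(sel, Sel) and sel.chain_ids is not None:
        missing = set(sel.chain_ids) - set(s.chain_ids)
        if missing:
            logger.warning("selection references unknown chain(s): %s",
                           ", ".join(sorted(missing)))
    out = Structure(s.id, [], s.source)
    for r in s.residues:
        atoms = [a.copy() for a in r.atoms if sel.matches_atom(r, a)]
        if atoms:
            out.residues.append(Residue(r.chain_id, r.seq_id, r.name, atoms))
    return out


def concat(parts: Iterable[Structure], id: str = "") -> Structure:
    """Concatenate structures into one (chain ids are kept as-is)."""
    out = Structure(id, [], "")
    for p in parts:
        out.residues.extend(r.copy() for r in p.residues)
    return out


# ---------------------------------------------------------------------------
# File input/output (gemmi-backed)
# ---------------------------------------------------------------------------

def _guess_format(path: str | Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    sfx = "".join(Path(path).suffixes).lower()
    if sfx.endswith(".cif") or sfx.endswith(".mmcif") or sfx.endswith(".cif.gz"):
        return "mmcif"
    return "pdb"


def _resolve_altlocs(residue) -> list:
    """Keep one atom per atom name: highest occupancy, ties by altloc label."""
    by_name: dict[str, list] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occ, a.altloc or ""))
        kept.append(group[0])
    kept.sort(key=lambda a: a.serial)
    return kept


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read an mmCIF or PDB file into a :class:`Structure`.

    Author (deposited) residue numbering is kept as the single numbering
    scheme.  Alternate locations are resolved to the highest-occupancy
    conformer (ties broken by altloc label).  Only the first model of a
    multi-model file is read.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _guess_format(path, format)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc

    out = Structure(id=st.name or path.stem, source=f"{path}:{fmt}")
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no model")
    model = st[0]
    for chain in model:
        for res in chain:
            atoms = []
            for atom in _resolve_altlocs(res):
                el = atom.element.name if atom.element else ""
                atoms.append(Atom(
                    name=atom.name,
                    element=el or "C",
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    is_hetero=res.het_flag == "H",
                ))
            if atoms:
                out.residues.append(
                    Residue(chain.name, res.seqid.num, res.name, atoms))
    if out.n_atoms == 0:
        raise EmptyStructureError(f"{path}: structure is empty")
    return out


def _disambiguate_chain_ids(s: Structure, one_char: bool) -> tuple[Structure, dict[str, str]]:
    """Rename chain ids that a format cannot represent; log the mapping."""
    ids = s.chain_ids
    mapping: dict[str, str] = {}
    if one_char:
        pool = list(string.ascii_uppercase + string.ascii_lowercase + string.digits)
        used = set(i for i in ids if len(i) == 1)
        for cid in ids:
            if len(cid) == 1:
                mapping[cid] = cid
                continue
            new = next((c for c in pool if c not in used), None)
            if new is None:
                raise ValueError("too many chains for PDB format")
            used.add(new)
            mapping[cid] = new
    else:
        mapping = {i: i for i in ids}
    changed = {k: v for k, v in mapping.items() if k != v}
    if changed:
        logger.info("chain ids renamed for output: %s",
                    ", ".join(f"{k}->{v}" for k, v in changed.items()))
        return s.renamed_chains(mapping), mapping
    return s, mapping


def write_structure(s: Structure, path: str | Path, format: str = "auto") -> dict[str, str]:
    """Write *s* to PDB or mmCIF.  Returns the chain-id mapping used.

    Chain ids a format cannot hold (PDB: one character) are renamed, and the
    mapping is logged and returned.
    """
    import gemmi

    if s.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    fmt = _guess_format(path, format)
    s2, mapping = _disambiguate_chain_ids(s, one_char=(fmt == "pdb"))

    st = gemmi.Structure()
    st.name = s.id or "model"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in s2.residues:
        if r.chain_id not in chains:
            chains[r.chain_id] = gemmi.Chain(r.chain_id)
        gres = gemmi.Residue()
        gres.name = r.name
        gres.seqid = gemmi.SeqId(r.seq_id, " ")
        gres.het_flag = "H" if any(a.is_hetero for a in r.atoms) else "A"
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            gres.add_atom(ga)
        chains[r.chain_id].add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return mapping
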