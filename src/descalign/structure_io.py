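"""Reading and writing protein structures, and per-residue virtual atoms.

Structures are parsed with :mod:`gemmi` (PDB and mmCIF dialects) into a
small immutable residue/atom model that the descriptor machinery works
on.  Only the first model of multi-model files is used, hydrogens are
dropped, and for alternate conformations the highest-occupancy conformer
is kept.  A residue is *proper* when it is one of the twenty standard
amino acids and carries the complete set of heavy atoms expected for its
type; only proper residues can seed or join descriptor elements.

Besides real atoms, two virtual side-chain representatives are provided:

``SCGC``
    the geometric (arithmetic) centre of the side-chain heavy atoms,
    directly dependent on the residue type;
``CBX``
    the C-beta–extended point, a fixed point on the ray CA -> CB beyond
    CB, i.e. the same point in space relative to the backbone regardless
    of residue type.  For glycine a virtual CB is first built from the
    backbone assuming ideal tetrahedral geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

log = logging.getLogger(__name__)

#: Default extension of the CBX point beyond CB along the CA->CB ray (A).
CBX_EXTENSION: float = 1.5

#: Heavy atoms expected for each standard amino acid (PDB atom names).
#: The terminal oxygen OXT is tolerated as an extra.
_BACKBONE = ("N", "CA", "C", "O")
STANDARD_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": _BACKBONE + ("CB",),
    "ARG": _BACKBONE + ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": _BACKBONE + ("CB", "CG", "OD1", "ND2"),
    "ASP": _BACKBONE + ("CB", "CG", "OD1", "OD2"),
    "CYS": _BACKBONE + ("CB", "SG"),
    "GLN": _BACKBONE + ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": _BACKBONE + ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": _BACKBONE,
    "HIS": _BACKBONE + ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": _BACKBONE + ("CB", "CG1", "CG2", "CD1"),
    "LEU": _BACKBONE + ("CB", "CG", "CD1", "CD2"),
    "LYS": _BACKBONE + ("CB", "CG", "CD", "CE", "NZ"),
    "MET": _BACKBONE + ("CB", "CG", "SD", "CE"),
    "PHE": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": _BACKBONE + ("CB", "CG", "CD"),
    "SER": _BACKBONE + ("CB", "OG"),
    "THR": _BACKBONE + ("CB", "OG1", "CG2"),
    "TRP": _BACKBONE
    + ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": _BACKBONE + ("CB", "CG1", "CG2"),
}

VIRTUAL_ATOM_KINDS = ("CA", "CBX", "SCGC")


class StructureParseError(ValueError):
    """Raised when a structure file cannot be read or has no usable model."""


class StructureFormatError(ValueError):
    """Raised for an unknown or unsupported structure format name."""


class VirtualAtomError(ValueError):
    """Raised when a (virtual) atom cannot be built for a residue."""


class ResidueLookupError(KeyError):
    """Raised when a residue id is not present in a structure."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: PDB atom name, element symbol, position in angstrom."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.name:
            raise ValueError("atom name must be non-empty")


ResidueId = tuple[str, int, str]  # (chain_id, seq_number, insertion_code)


@dataclass(frozen=True)
class Residue:
    """A residue with its heavy atoms and the proper-residue flag."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: tuple[AtomRecord, ...]
    is_proper: bool = field(default=False)

    @property
    def rid(self) -> ResidueId:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise VirtualAtomError(
            f"residue {self.chain_id}/{self.seq_number}{self.insertion_code} "
            f"({self.res_name}) has no atom {name!r}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def side_chain_atoms(self) -> tuple[AtomRecord, ...]:
        """Heavy atoms beyond the backbone (CB and outward)."""
        bb = set(_BACKBONE) | {"OXT"}
        return tuple(a for a in self.atoms if a.name not in bb)


@dataclass(frozen=True)
class Structure:
    """An ordered collection of residues grouped by chain."""

    id: str
    chains: dict  # chain_id -> tuple[Residue, ...] in chain order
    source_format: str = "PDB"

    def residues(self) -> Iterable[Residue]:
        for cid in self.chains:
            yield from self.chains[cid]

    def proper_residues(self) -> list[Residue]:
        return [r for r in self.residues() if r.is_proper]

    def get(self, rid: ResidueId) -> Residue:
        for r in self.chains.get(rid[0], ()):
            if r.rid == rid:
                return r
        raise ResidueLookupError(f"no residue {rid} in structure {self.id}")

    def __len__(self) -> int:
        return sum(len(c) for c in self.chains.values())


def _is_proper(res_name: str, atom_names: set[str]) -> bool:
    expected = STANDARD_HEAVY_ATOMS.get(res_name)
    if expected is None:
        return False
    return set(expected) <= atom_names


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins, ties broken by altloc identifier order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def _coor_format(fmt: str) -> gemmi.CoorFormat:
    key = fmt.strip().lower()
    if key in ("pdb",):
        return gemmi.CoorFormat.Pdb
    if key in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    if key in ("auto", "detect"):
        return gemmi.CoorFormat.Detect
    raise StructureFormatError(f"unknown structure format {fmt!r}")


def parse_structure(path, format: str = "auto") -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Hydrogens (and deuteriums) are excluded, waters and other
    non-standard residues are kept but flagged improper, and only the
    first model is used.  Chain identifiers, residue numbers and
    insertion codes are preserved verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = _coor_format(format)
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path}: no model found")
    model = st[0]
    fmt_name = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"

    chains: dict[str, tuple[Residue, ...]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            groups: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                groups.setdefault(atom.name, []).append(atom)
            atoms = []
            for name in groups:
                a = _pick_altloc(groups[name])
                atoms.append(
                    AtomRecord(
                        name=name,
                        element=a.element.name,
                        position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    )
                )
            atoms_t = tuple(atoms)
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    res_name=res.name,
                    atoms=atoms_t,
                    is_proper=_is_proper(res.name, {a.name for a in atoms_t}),
                )
            )
        if residues:
            chains[chain.name] = tuple(residues)
    if not chains:
        raise StructureParseError(f"{path}: no atom records found")
    return Structure(id=st.name or path.stem, chains=chains, source_format=fmt_name)


def _gly_virtual_cb(residue: Residue) -> np.ndarray:
    """Ideal-geometry CB for glycine, built from N, CA and C.

    Uses the standard tetrahedral construction: with b = CA - N,
    c = C - CA and a = b x c, CB = CA - 0.58273431 a + 0.56802827 b
    - 0.54067466 c (coefficients reproduce the canonical 1.53 A bond and
    tetrahedral angles for ideal backbones).
    """
    n = residue.atom("N").position
    ca = residue.atom("CA").position
    c = residue.atom("C").position
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return ca - 0.58273431 * a + 0.56802827 * b - 0.54067466 * cc


def virtual_atom(
    residue: Residue, kind: str, cbx_extension: float = CBX_EXTENSION
) -> np.ndarray:
    """Position of a real or virtual representative atom of ``residue``.

    ``kind`` is ``"CA"``, ``"CBX"``, ``"SCGC"`` or any real heavy-atom
    name.  SCGC of glycine (no side-chain heavy atoms) falls back to the
    CA position; CBX of glycine uses an ideal-geometry virtual CB.
    """
    if kind == "CA":
        return residue.atom("CA").position
    if kind == "SCGC":
        side = residue.side_chain_atoms()
        if not side:
            log.debug(
                "SCGC of %s %s/%s: no side-chain atoms, using CA",
                residue.res_name,
                residue.chain_id,
                residue.seq_number,
            )
            return residue.atom("CA").position
        return np.mean([a.position for a in side], axis=0)
    if kind == "CBX":
        ca = residue.atom("CA").position
        if residue.has_atom("CB"):
            cb = residue.atom("CB").position
        elif residue.res_name == "GLY":
            cb = _gly_virtual_cb(residue)
        else:
            raise VirtualAtomError(
                f"residue {residue.chain_id}/{residue.seq_number} "
                f"({residue.res_name}) lacks CB for CBX"
            )
        d = cb - ca
        norm = float(np.linalg.norm(d))
        if norm < 1e-9:
            raise VirtualAtomError(
                f"degenerate CA-CB geometry in residue "
                f"{residue.chain_id}/{residue.seq_number}"
            )
        return ca + d * (norm + cbx_extension) / norm
    # a plain heavy-atom name
    return residue.atom(kind).position


def _to_gemmi(structure: Structure, rids: Iterable[ResidueId]) -> gemmi.Structure:
    wanted = list(rids)
    if not wanted:
        raise ValueError("empty residue selection")
    seen = set(wanted)
    missing = [rid for rid in wanted if _find(structure, rid) is None]
    if missing:
        raise ResidueLookupError(f"unknown residue ids: {missing}")
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        any_res = False
        for r in residues:
            if r.rid not in seen:
                continue
            gr = gemmi.Residue()
            gr.name = r.res_name
            gr.seqid = gemmi.SeqId(r.seq_number, r.insertion_code or " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = 1.0
                gr.add_atom(ga)
            chain.add_residue(gr)
            any_res = True
        if any_res:
            model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _find(structure: Structure, rid: ResidueId) -> Optional[Residue]:
    for r in structure.chains.get(rid[0], ()):
        if r.rid == rid:
            return r
    return None


def write_substructure(
    structure: Structure, rids: Iterable[ResidueId], path, format: str = "PDB"
) -> None:
    """Write the selected residues, with original identifiers, to a file."""
    fmt = format.strip().lower()
    st = _to_gemmi(structure, rids)
    path = Path(path)
    if fmt == "pdb":
        path.write_text(st.make_pdb_string())
    elif fmt in ("mmcif", "cif"):
        path.write_text(st.make_mmcif_document().as_string())
    else:
        raise StructureFormatError(f"unknown structure format {format!r}")
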