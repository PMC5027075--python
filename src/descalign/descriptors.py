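"""Building local structural descriptors.

A *descriptor* captures the structural neighbourhood of one central
residue: every proper residue in contact with the centre (per a contact
expression) is expanded with its chain neighbours into an *element* — a
contiguous run of an odd number of residues (default 5) centred on it —
and overlapping or abutting elements merge into *segments*.  The central
element, built around the centre itself, is distinguished.  A *duplex*
pairs the central element with one other element; duplexes are the unit
actually aligned between two descriptors, because the shared central
element pins the pair in space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .contact_expr import ContactExpression, EvaluationError, evaluate
from .structure_io import Residue, ResidueId, Structure, virtual_atom

log = logging.getLogger(__name__)

DEFAULT_ELEMENT_SIZE = 5
DEFAULT_REPRESENTATIVE_KINDS = ("CA", "SCGC")


@dataclass(frozen=True)
class Element:
    """A contiguous odd-length run of proper residues centred on one residue."""

    residues: tuple  # tuple[Residue, ...], chain order
    is_central: bool = False

    def __post_init__(self):
        if len(self.residues) % 2 != 1:
            raise ValueError("element size must be odd")

    @property
    def size(self) -> int:
        return len(self.residues)

    @property
    def center_residue(self) -> Residue:
        return self.residues[len(self.residues) // 2]

    @property
    def rids(self) -> tuple:
        return tuple(r.rid for r in self.residues)

    def run(self) -> tuple[str, int, int]:
        """(chain, first seq number, last seq number) of the run."""
        return (
            self.residues[0].chain_id,
            self.residues[0].seq_number,
            self.residues[-1].seq_number,
        )


@dataclass(frozen=True)
class Segment:
    """A maximal contiguous chain fragment covered by merged elements."""

    residues: tuple  # tuple[Residue, ...]
    member_elements: tuple  # tuple[Element, ...]

    @property
    def size(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Descriptor:
    """A central element plus the elements of all in-contact residues."""

    name: str
    central_element: Element
    other_elements: tuple  # tuple[Element, ...], chain order
    segments: tuple  # tuple[Segment, ...]
    element_size: int = DEFAULT_ELEMENT_SIZE
    representative_atom_kinds: tuple = DEFAULT_REPRESENTATIVE_KINDS

    @property
    def n(self) -> int:
        """Number of non-central elements."""
        return len(self.other_elements)

    @property
    def element_count(self) -> int:
        return self.n + 1

    @property
    def elements(self) -> tuple:
        return (self.central_element,) + self.other_elements

    @property
    def residue_set(self) -> tuple:
        """All covered residues, deduplicated, in canonical chain order."""
        return _union_residues(self.elements)

    @property
    def residue_count(self) -> int:
        return len(self.residue_set)

    @property
    def segment_count(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class Duplex:
    """The central element of a descriptor paired with one other element.

    ``residues`` is the union of the two elements' residues (shared
    residues once) in canonical chain order; ``atoms`` stacks the
    representative atoms of every residue, kind-major within residue.
    """

    central: Element
    other: Element
    residues: tuple
    atoms: np.ndarray  # (len(residues) * len(kinds), 3)

    @property
    def residue_count(self) -> int:
        return len(self.residues)


def _canonical_sort_key(residue: Residue):
    return (residue.chain_id, residue.seq_number, residue.insertion_code)


def _union_residues(elements: Sequence[Element]) -> tuple:
    seen: dict[ResidueId, Residue] = {}
    for el in elements:
        for r in el.residues:
            seen.setdefault(r.rid, r)
    return tuple(sorted(seen.values(), key=_canonical_sort_key))


def representative_atoms(
    residues: Sequence[Residue], kinds: Sequence[str]
) -> np.ndarray:
    """Representative-atom coordinates, residue-major then kind order."""
    coords = [virtual_atom(r, k) for r in residues for k in kinds]
    return np.array(coords, dtype=float)


def find_contact_residues(
    structure: Structure, center: Residue, expr: ContactExpression
) -> list[Residue]:
    """All proper residues (any chain) in contact with ``center``.

    A candidate whose atoms cannot be resolved under the expression
    (e.g. a named atom absent from its side chain) is skipped with a
    debug log rather than aborting the scan.
    """
    if not center.is_proper:
        raise ValueError(f"descriptor centre {center.rid} is not a proper residue")
    out: list[Residue] = []
    for res in structure.residues():
        if not res.is_proper or res.rid == center.rid:
            continue
        try:
            if evaluate(expr, center, res):
                out.append(res)
        except EvaluationError as exc:
            log.debug("skipping candidate %s: %s", res.rid, exc)
    out.sort(key=_canonical_sort_key)
    return out


def expand_to_element(
    structure: Structure,
    residue: Residue,
    element_size: int = DEFAULT_ELEMENT_SIZE,
    is_central: bool = False,
) -> Optional[Element]:
    """Expand a residue into its element, or ``None`` if impossible.

    The element is the run of ``element_size`` residues centred on
    ``residue``: the flank on each side must exist in the chain, be
    proper, and be numbered consecutively without insertion codes.
    Residues near chain termini or numbering gaps yield ``None`` —
    partial elements are never built.
    """
    if element_size < 3 or element_size % 2 != 1:
        raise ValueError("element_size must be an odd integer >= 3")
    chain = structure.chains.get(residue.chain_id, ())
    try:
        idx = next(i for i, r in enumerate(chain) if r.rid == residue.rid)
    except StopIteration:
        raise ValueError(f"residue {residue.rid} not found in structure")
    half = element_size // 2
    lo, hi = idx - half, idx + half
    if lo < 0 or hi >= len(chain):
        log.debug("residue %s too close to a chain terminus", residue.rid)
        return None
    run = chain[lo : hi + 1]
    for a, b in zip(run, run[1:]):
        if b.seq_number - a.seq_number != 1 or a.insertion_code or b.insertion_code:
            log.debug("numbering gap next to residue %s", residue.rid)
            return None
    if not all(r.is_proper for r in run):
        log.debug("improper residue inside the element of %s", residue.rid)
        return None
    return Element(residues=tuple(run), is_central=is_central)


def _merge_segments(elements: Sequence[Element]) -> tuple:
    """Merge overlapping or abutting element runs into segments, per chain."""
    by_chain: dict[str, list[Element]] = {}
    for el in elements:
        by_chain.setdefault(el.residues[0].chain_id, []).append(el)
    segments: list[Segment] = []
    for cid in sorted(by_chain):
        els = sorted(by_chain[cid], key=lambda e: e.residues[0].seq_number)
        group: list[Element] = [els[0]]
        end = els[0].residues[-1].seq_number
        for el in els[1:]:
            start = el.residues[0].seq_number
            if start <= end + 1:  # overlap or zero gap -> same segment
                group.append(el)
                end = max(end, el.residues[-1].seq_number)
            else:
                segments.append(
                    Segment(residues=_union_residues(group), member_elements=tuple(group))
                )
                group = [el]
                end = el.residues[-1].seq_number
        segments.append(
            Segment(residues=_union_residues(group), member_elements=tuple(group))
        )
    return tuple(segments)


def descriptor_name(structure: Structure, center: Residue) -> str:
    return f"{structure.id}_{center.chain_id}_{center.seq_number}_{center.res_name}"


def build_descriptor(
    structure: Structure,
    center: Residue,
    expr: ContactExpression,
    element_size: int = DEFAULT_ELEMENT_SIZE,
    representative_atom_kinds: Sequence[str] = DEFAULT_REPRESENTATIVE_KINDS,
    min_segments: int = 0,
    min_elements: int = 0,
    min_residues: int = 0,
) -> Optional[Descriptor]:
    """Build the descriptor around ``center``, or ``None``.

    ``None`` is returned when the centre itself cannot form an element,
    or when the finished descriptor fails any of the minimum-count
    filters (segments, elements, residues).  Contact residues that cannot
    form a complete element are dropped; duplicate element runs are
    collapsed.
    """
    central = expand_to_element(structure, center, element_size, is_central=True)
    if central is None:
        log.debug("centre %s cannot form a central element", center.rid)
        return None
    others: list[Element] = []
    seen_runs = {central.rids}
    for res in find_contact_residues(structure, center, expr):
        el = expand_to_element(structure, res, element_size)
        if el is None:
            continue
        if el.rids in seen_runs:
            continue
        seen_runs.add(el.rids)
        others.append(el)
    others.sort(key=lambda e: _canonical_sort_key(e.center_residue))
    desc = Descriptor(
        name=descriptor_name(structure, center),
        central_element=central,
        other_elements=tuple(others),
        segments=_merge_segments([central, *others]),
        element_size=element_size,
        representative_atom_kinds=tuple(representative_atom_kinds),
    )
    if (
        desc.segment_count < min_segments
        or desc.element_count < min_elements
        or desc.residue_count < min_residues
    ):
        log.debug("descriptor %s rejected by count filters", desc.name)
        return None
    return desc


def make_duplex(
    central: Element, other: Element, kinds: Sequence[str]
) -> Duplex:
    residues = _union_residues([central, other])
    return Duplex(
        central=central,
        other=other,
        residues=residues,
        atoms=representative_atoms(residues, kinds),
    )


def make_duplexes(descriptor: Descriptor) -> list[Duplex]:
    """One duplex per non-central element, in element order."""
    kinds = descriptor.representative_atom_kinds
    return [
        make_duplex(descriptor.central_element, el, kinds)
        for el in descriptor.other_elements
    ]
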