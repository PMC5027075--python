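import numpy as np
import pytest

from descalign import FixtureSpec, generate_descriptor, generate_structure
from descalign.structure_io import AtomRecord, Residue, Structure


@pytest.fixture(scope="session")
def helix_structure():
    return generate_structure(FixtureSpec(seed=7, chain_length=30, geometry="helix"))


@pytest.fixture(scope="session")
def helix_descriptor():
    return generate_descriptor(FixtureSpec(seed=7, chain_length=30, geometry="helix"))


def make_residue(seq, positions, chain="A", res_name=None, names=None):
    """A minimal hand-made residue from a dict/list of atom positions.

    Defaults to an alanine-like atom set (N, CA, C, O, CB) so the residue
    is proper; SCGC then coincides with CB.
    """
    if names is None:
        names = ["N", "CA", "C", "O", "CB"]
    elements = [n[0] for n in names]
    atoms = tuple(
        AtomRecord(name=n, element=e, position=np.asarray(p, dtype=float))
        for n, e, p in zip(names, elements, positions)
    )
    return Residue(
        chain_id=chain,
        seq_number=seq,
        insertion_code="",
        res_name=res_name or "ALA",
        atoms=atoms,
        is_proper=res_name in (None, "ALA"),
    )


def line_residue(seq, origin, chain="A"):
    """An ALA residue with a compact, non-degenerate atom arrangement."""
    o = np.asarray(origin, dtype=float)
    return make_residue(
        seq,
        [
            o + (-1.4, 0.2, 0.0),  # N
            o,  # CA
            o + (1.4, -0.2, 0.0),  # C
            o + (1.6, -1.4, 0.3),  # O
            o + (0.1, 1.5, 0.4),  # CB
        ],
        chain=chain,
    )
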