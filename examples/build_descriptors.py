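"""Identify descriptors in a structure.

Builds a small synthetic helical chain, then constructs one descriptor
per proper residue using the standard side-chain-centre contact
expression, and prints the index that the ``descalign identify``
subcommand would write: descriptor name, number of segments, elements
and residues.  Elements are 5-residue backbone runs; a descriptor is the
central element plus one element per residue in contact with the centre.
"""

from descalign import (
    FixtureSpec,
    build_descriptor,
    default_expression,
    generate_structure,
)

structure = generate_structure(FixtureSpec(seed=7, chain_length=30, geometry="helix"))
expr = default_expression()
print(f"structure {structure.id}: {len(structure)} residues")
print(f"contact expression: {expr.text}")
print()
print(f"{'name':28s} {'segments':>8s} {'elements':>8s} {'residues':>8s}")
for residue in structure.proper_residues():
    desc = build_descriptor(structure, residue, expr)
    if desc is None:
        continue  # too close to a terminus to form the central element
    print(
        f"{desc.name:28s} {desc.segment_count:8d} "
        f"{desc.element_count:8d} {desc.residue_count:8d}"
    )
print()
print("Each row is one local structural motif: a helical centre picks up")
print("its i+-1 and i+-3/4 neighbours, which merge into a single segment.")
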