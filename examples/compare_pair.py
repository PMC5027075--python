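"""Structurally compare a descriptor pair under all four algorithms.

Generates a sheet-like descriptor of eight elements and a rigidly
moved, mildly noised copy (sigma = 0.3 A), then runs the three Hungarian-method
algorithms and the exact backtracking search.  For a similar pair the
report shows the alignment length N (aligned duplex pairs + the central
pair), the fraction of elements and residues covered, and the global
RMSD of the merged aligned substructures — the same numbers the
``descalign compare`` subcommand prints.
"""

from descalign import FixtureSpec, compare, generate_pair

desc_a, desc_b = generate_pair(
    FixtureSpec(seed=2, target_element_count=7), perturbation=0.3
)
print(f"A: {desc_a.name}  ({desc_a.element_count} elements, "
      f"{desc_a.residue_count} residues)")
print(f"B: {desc_b.name}  (rigid motion + 0.3 A noise copy)")
print()
for algorithm_id in (1, 2, 3, 4):
    result = compare(desc_a, desc_b, algorithm_id)
    if result.similar:
        al = result.alignment
        print(
            f"algorithm {algorithm_id}: similar  "
            f"N={al.n_aligned}  "
            f"elements={result.element_ratio_achieved:.2f}  "
            f"residues={result.residue_ratio_achieved:.2f}  "
            f"global RMSD={al.global_rmsd:.2f} A  "
            f"total cost={al.total_cost:.2f}"
        )
    else:
        print(f"algorithm {algorithm_id}: not similar "
              f"({result.rejection_reason.value})")
print()
print("All four agree here: a 0.3 A perturbation keeps every duplex pair")
print("well under the 3.5 A cost ceiling, so the full-size alignment is")
print("feasible and the global RMSD stays near the noise level.")
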