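# descalign

Identification and structural comparison of **local protein descriptors** —
with the comparison solved as a **maximum-size assignment** problem.

## The problem

A *descriptor* captures the structural neighbourhood of one central residue
of a protein: every residue in spatial contact with the centre is expanded
with its chain neighbours into an *element* (a contiguous backbone run of an
odd number of residues, 5 by default), overlapping elements merge into
*segments*, and the element built around the centre itself is the *central
element*. Descriptors record long-range tertiary contacts, so structurally
similar descriptors recur across unrelated folds; comparing them efficiently
is a building block for model quality assessment and fragment-based
structure analysis.

Two descriptors `A = {a*, a1..an}` and `B = {b*, b1..bm}` are compared
through their *duplexes* `d_Ai = (a*, ai)`, `d_Bj = (b*, bj)` — the shared
central element pins each pair in space. The **greatest structural
alignment** is the largest pairing of duplexes satisfying:

1. cardinality balance `4/5·|B| ≤ |A| ≤ 5/4·|B|`;
2. preserved centres, `RMSD(a*, b*) ≤ 1.2 Å`;
3. every aligned duplex pair has `RMSD ≤ 3.5 Å` (pairs with different atom
   counts are incomparable and carry a sentinel cost `M`);
4. the alignment length `N` (duplex pairs + the central pair) satisfies
   `N ≥ 4/5·|A|, 4/5·|B|`, and the aligned residues cover at least `2/3`
   of both descriptors' residues;
5. the merged aligned substructures superpose with global `RMSD ≤ 3.5 Å`.

Finding the largest duplex pairing with total cost at most `L = f·K`
(`f ∈ [1.75, 2.33]`) is the **maximum-size assignment (MA)** problem on the
duplex-pair RMSD cost matrix `C = [c_ij]`:

```
max  Σ x_ij      s.t.  Σ c_ij·x_ij ≤ L,   Σ_i x_ij ≤ 1,   Σ_j x_ij ≤ 1
```

MA is equivalent to the classic square assignment problem: pad `C` to an
`(n+m−K) × (n+m−K)` matrix with zero rows/columns and one all-`M` corner
block, and a minimum-cost perfect assignment solves the size-`K` instance.
Four algorithms search over the admissible sizes
`K = min(n,m), …, ⌈4/5·(max(n,m)+1)⌉ − 1`:

| id | strategy |
|----|----------|
| 1  | first MA-feasible `K` (largest first), verified once |
| 2  | all admissible `K`, best verified candidate (most duplexes, then most residues) |
| 3  | as 2, plus *partial solutions*: cost-sorted prefixes with pairs skipped when they unbalance the merged residue counts |
| 4  | exact backtracking over all duplex injections (most duplexes, then residues, then lowest mean duplex RMSD) |

Algorithms 1–3 run in polynomial time via the Hungarian method; algorithm 4
is exponential but exact, and is the reference the others are measured
against. Comparison is symmetric: `compare(A, B)` and `compare(B, A)` give
the same classification, `N` and global RMSD.

## A worked example

```sh
$ python examples/compare_pair.py
A: synth2_A_17_CYS  (8 elements, 24 residues)
B: synth2_A_17_CYS_copy  (rigid motion + 0.3 A noise copy)

algorithm 1: similar  N=8  elements=1.00  residues=1.00  global RMSD=0.45 A  total cost=2.68
algorithm 2: similar  N=8  elements=1.00  residues=1.00  global RMSD=0.45 A  total cost=2.68
algorithm 3: similar  N=8  elements=1.00  residues=1.00  global RMSD=0.45 A  total cost=2.68
algorithm 4: similar  N=8  elements=1.00  residues=1.00  global RMSD=0.45 A  total cost=2.68
```

All 8 elements (7 duplex pairs + the central pair, `N = 8`) are aligned,
covering 100 % of both descriptors' elements and residues; the merged
substructures superpose at 0.45 Å — the noise level of the copy — and the
total assignment cost 2.68 Å is far below `L = 2.33·7`. The other example
scripts (`examples/build_descriptors.py`, `examples/solve_cost_matrix.py`)
walk through descriptor identification and the bare assignment solver.

## Command line

```sh
descalign identify structure.pdb --outdir descs        # one descriptor per proper residue + TSV index
descalign compare descs/a.pdb descs/b.pdb --algorithm 3 --write-aligned
descalign solve-matrix costs.tsv -f 2.33               # MA solver on a TSV cost matrix
descalign make-fixtures --seed 7 --geometry sheet      # synthetic test structures
```

Structures are read and written in PDB and mmCIF (default PDB). Contact
residues are selected by a configurable boolean expression over atom
distances, e.g. the package default

```
OR(DISTANCE:SCGC <= 6.5, AND(DISTANCE:SCGC <= DISTANCE:CA - 0.75, DISTANCE:SCGC <= 8.0))
```

with logical `OR/AND/NOT`, relations `< <= = >= >` (Unicode `≤ ≥` accepted),
arithmetic `+`/`-`, and distance terms naming any heavy atom or the virtual
atoms `CA`, `CBX` (Cβ-extended point) and `SCGC` (side-chain geometric
centre). `DISTANCE:X` pairs atom `X` of the centre with atom `X` of the
candidate; `DISTANCE:X;Y` pairs atom `X` of the centre with atom `Y` of the
candidate. The full grammar is documented in
`descalign/contact_expr.py`.

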