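# Methods

This note documents the model implemented by `descalign`, the numerical
and design choices made where the problem statement leaves room, and what
the synthetic-data generator does and does not emulate.

## Descriptor model

A structure is parsed (gemmi, PDB/mmCIF, first model only, hydrogens
dropped, highest-occupancy altloc kept) into an immutable residue/atom
model. A residue is **proper** when it is one of the twenty standard amino
acids and carries every heavy atom expected for its type (OXT tolerated);
only proper residues participate in descriptors. Contact detection between
a centre and a candidate residue evaluates a user-supplied boolean
expression over inter-residue atom distances. Two virtual atoms are
available besides real ones:

* **SCGC** — arithmetic mean of the side-chain heavy atoms (CB and
  outward). Glycine has none, so SCGC falls back to CA; this keeps the
  function total and is logged at debug level.
* **CBX** — the point on the ray CA→CB at distance |CA−CB| + 1.5 Å from
  CA. The 1.5 Å extension is a package default exposed as a parameter
  (`cbx_extension`); it realises a side-chain surrogate at a fixed offset
  relative to the backbone, independent of residue type. For glycine a
  virtual CB is first constructed from N, CA, C with the standard ideal
  tetrahedral coefficients.

Contact residues are expanded into **elements**: runs of `element_size`
(odd, default 5) consecutive residues centred on the contact. A run must
be complete — inside the chain, properly numbered (consecutive numbers, no
insertion codes), all residues proper — otherwise the contact is dropped
entirely rather than truncated. Elements whose runs overlap or abut merge
into **segments**. Contacts are accepted from any chain of the structure,
but elements never span chains. A candidate residue that cannot resolve an
atom named by the expression (e.g. `DISTANCE:SG` on a serine) is skipped
with a debug log instead of aborting the identification run.

## Comparison model

Descriptor pairs are compared through duplexes (central element + one
other element). Costs are `RMSD(d_Ai, d_Bj)` over the representative atoms
(default kinds CA and SCGC, residue-major order, union of the two
elements' residues with shared residues counted once). RMSD is the Kabsch
SVD superposition with reflection correction; it is defined only for equal
point counts, so duplex pairs with different residue counts (different
central-element overlap) receive the sentinel `M = 10^6`, as does any pair
above the 3.5 Å per-pair ceiling — such a pair could never join a feasible
alignment, and `M` comfortably exceeds every reachable cost limit
`L = f·K ≤ 2.33·K`.

Costs are rounded to two decimals and scaled by 100 to integers
internally, making all feasibility arithmetic exact; the cost-limit test
is `scaled_total ≤ round(100·f·K)`. The global-RMSD feasibility check
(≤ 3.5 Å) uses full precision, since it is a geometric acceptance
criterion rather than part of the integer cost model.

The maximum-size assignment instance for size `K` is transformed to a
square assignment instance of order `n + m − K` (zero padding rows and
columns, one all-`M` corner block) and solved by
`scipy.optimize.linear_sum_assignment`. Ties between cost-equal optima are
broken deterministically to the lexicographically smallest pair set
(row-major) by fixing, row by row, the smallest column that still admits
an optimal completion — an `O(n²)` loop of re-solves, negligible at
descriptor scale.

The admissible sizes are `K = min(n,m)` down to
`⌈4/5·(max(n,m)+1)⌉ − 1`, i.e. exactly the sizes whose alignment length
`N = K+1` covers at least 4/5 of the larger descriptor. One consequence
worth noting: whenever the cardinality precheck `4/5·|B| ≤ |A| ≤ 5/4·|B|`
passes, this range is never empty, so the "no admissible K" rejection can
only occur for descriptors with no duplexes at all (`n = 0`).

### Merged substructures and the residue map

A candidate pairing is verified by merging, per side, the central element
with the paired elements (shared residues once). The two merged sides must
contain equally many residues — otherwise no RMSD is defined and the
candidate is rejected (`atom-count`). The residue correspondence is
positional between the two canonically ordered merged sides; with equal
counts and per-element positional pairing this is the unique order
-preserving bijection. Global RMSD is computed over the representative
atoms of the mapped residues.

### The four algorithms

* **Algorithm 1** stops at the first MA-feasible `K` (largest first). When
  the cheapest size-`K` assignment is spoiled *only* by selected `M`
  cells, the regular-cost subset is salvaged as a candidate of size `K′`
  (accepted if `K′` is still admissible and within `f·K′`) before moving
  to the next `K` — the sub-solution shortcut is part of the `K` loop.
* **Algorithm 2** collects one candidate per admissible `K` and picks the
  verified candidate with the most duplexes, ties broken by aligned
  residues.
* **Algorithm 3** additionally derives partial solutions from each `K`
  solution: pairs sorted by cost ascending, every prefix of length
  ≥ K_min considered, pairs added one by one and skipped when they would
  unbalance the merged residue counts; partials within `f·size` compete
  with the full solutions. Prefixes shorter than K_min are not generated —
  they cannot reach an admissible size.
* **Algorithm 4** (exact) backtracks over all injections of A's duplexes
  into B's restricted to comparable pairs (cost ≤ 3.5 Å), verifies every
  candidate of admissible size, and selects by duplex count, then aligned
  residue count, then lowest mean duplex RMSD. The relative order of the
  last two criteria is genuinely ambiguous in the problem statement; the
  implemented order is exposed as `ComparisonParams.tiebreak_residues_first`.
  Branches are pruned only when they cannot reach the incumbent's duplex
  count, which never discards a potentially better candidate, so the
  search remains exact.

Rejections carry an enumerated reason (`cardinality`, `central`,
`no-admissible-K`, `cost-limit`, `atom-count`, `global-rmsd`,
`element-ratio`, `residue-ratio`) for testability.

### Symmetry

The assignment model is symmetric up to tie-breaking (the transposed cost
matrix has the same optima), but tie-breaking itself is direction
-dependent. `compare()` therefore orders the two descriptors canonically
(by duplex count, residue count, name, then a coordinate digest) before
searching and maps the result back to the caller's order, which makes
`compare(A, B)` and `compare(B, A)` agree exactly in classification, `N`,
aligned residues and global RMSD.

## Parameters

| parameter | default | meaning |
|-----------|---------|---------|
| `element_size` | 5 | residues per element (odd) |
| `central_rmsd_max` | 1.2 Å | centre preservation bound |
| `pair_rmsd_max` | 3.5 Å | per-duplex-pair cost ceiling |
| `global_rmsd_max` | 3.5 Å | merged-substructure bound |
| `element_ratio` | 4/5 | minimum element coverage (via `N`) |
| `residue_ratio` | 2/3 | minimum residue coverage |
| `f` | 2.33 | cost-limit factor, `L = f·K`; meaningful range `[1/2·3.5, 2/3·3.5]` |
| `M` | 10⁶ | sentinel for incomparable/over-threshold pairs |
| `cbx_extension` | 1.5 Å | CBX offset beyond CB |
| representative kinds | CA, SCGC | atoms used for costs and global RMSD |

Lower `f` is more stringent: fewer assignments fit under `L`, so fewer
pairs classify as similar, but accepted alignments are tighter. The
similarity set grows monotonically with `f` for the all-K strategies.

## Synthetic data

The generator builds toy polypeptides sufficient to exercise every code
path without external data: CA traces at realistic 3.8 ± 0.2 Å spacing as
an extended strand, an ideal α-helix (2.3 Å radius, 1.5 Å rise,
100°/residue), or a meandering sheet of straight strands packed around a
central one; backbone N/C/O, CB and 1–3 pseudo-side-chain atoms matching
the atom inventories of real ALA/SER/CYS/VAL/THR are hung off local
frames, so every residue is proper. Element counts from about 3
(extended: only i±1 contacts) to 11 (six packed strands) are reached by
template selection; a requested target count picks the deterministic
template whose achieved count is closest. Descriptor pairs are made by
rigidly moving a copy and adding isotropic Gaussian noise per atom.

What the generator does *not* emulate: real side-chain rotamers and
chemistry, Ramachandran-valid backbones, crystallographic artefacts
(altlocs, gaps, insertion codes appear only in hand-written test inputs),
and the shape diversity of real folds — its duplexes are more
self-similar than real ones along a strand, and less diverse across
families. Passing tests therefore demonstrate the correctness of the
combinatorics and geometry, not biological benchmarking; coverage
statistics on real descriptor libraries are out of scope here.

Test problem sizes were chosen to keep the full suite in the minutes
range on one core: the exhaustive MA-equivalence battery enumerates all
cost matrices with `n, m ≤ 3` over entry alphabet {0, 1, 2, M} (≈ 0.4 M
matrices, > 10⁶ decision comparisons), the Hungarian check uses 1000
random matrices up to 6×6 against factorial brute force, and the
dominance/symmetry population holds 252 descriptor pairs spanning element
counts 3–11 and perturbations 0–5 Å.

## Known limitations

* RNA structures are not modelled; the CLI accepts `--molecule-type rna`
  only to report it unsupported.
* Multi-model NMR files use the first model; assemblies are not expanded.
* Insertion codes are preserved through I/O but break element contiguity
  by design (a numbered insertion has no well-defined ±2 neighbourhood).
* Algorithm 4 is exponential in the worst case; for descriptors whose
  duplexes are mutually near-identical (long regular helices) its search
  can grow combinatorially even with pruning.
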