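"""Structural comparison of descriptor pairs.

Two descriptors A (central element plus ``n`` others) and B (central
plus ``m`` others) are *structurally similar* when a structural
alignment of their duplex sets exists that satisfies all of:

1. cardinality balance: ``4/5 |B| <= |A| <= 5/4 |B|`` (element counts);
2. preserved centres: ``RMSD(a_*, b_*) <= 1.2`` A;
3. every aligned duplex pair has RMSD <= 3.5 A (incomparable pairs —
   different atom counts — are excluded outright);
4. the alignment length ``N`` (aligned duplex pairs + the central pair)
   covers at least 4/5 of both descriptors' elements, and the aligned
   residues cover at least 2/3 of both descriptors' residues;
5. the global RMSD of the merged aligned substructures is <= 3.5 A.

Four algorithms search for the greatest such alignment.  Algorithms 1-3
solve the maximum-size assignment relaxation through the Hungarian
method (first-feasible / all-K / all-K-plus-partial-solutions flavours);
Algorithm 4 is an exact backtracking search over all duplex injections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from . import assignment as asg
from .assignment import AssignmentSolution, CostMatrix
from .descriptors import (
    Descriptor,
    Duplex,
    Element,
    make_duplexes,
    representative_atoms,
    _union_residues,
)
from .geometry import M_SENTINEL, rmsd_guarded, superpose
from .structure_io import Residue, Structure

log = logging.getLogger(__name__)


class Rejection(Enum):
    """Why a descriptor pair (or one candidate alignment) was rejected."""

    CARDINALITY = "cardinality"
    CENTRAL = "central"
    NO_K = "no-admissible-K"
    COST_LIMIT = "cost-limit"
    ATOM_COUNT = "atom-count"
    GLOBAL_RMSD = "global-rmsd"
    ELEMENT_RATIO = "element-ratio"
    RESIDUE_RATIO = "residue-ratio"


@dataclass(frozen=True)
class ComparisonParams:
    """All thresholds of the similarity definition.

    ``f`` scales the total-cost limit ``L = f * K`` of the assignment
    stage; the meaningful range is ``[1/2 * 3.5, 2/3 * 3.5]``, i.e.
    1.75 (most stringent) to 2.33 (default).
    """

    central_rmsd_max: float = 1.2
    pair_rmsd_max: float = 3.5
    global_rmsd_max: float = 3.5
    element_ratio: float = 4 / 5
    residue_ratio: float = 2 / 3
    f: float = 2.33
    big: float = M_SENTINEL
    tiebreak_residues_first: bool = True
    """Exact-search tie-break order: duplex count, then aligned residue
    count, then average duplex RMSD.  Set ``False`` to prefer average
    RMSD over residue count."""


@dataclass(frozen=True)
class Alignment:
    """An accepted greatest structural alignment."""

    duplex_pairs: tuple  # ((i, j), ...) indices into D_A x D_B
    residue_map: tuple  # ((rid_A, rid_B), ...)
    total_cost: float  # sum of aligned duplex costs
    global_rmsd: float
    aligned_residue_counts: tuple  # (|aligned A|, |aligned B|)

    @property
    def n_aligned(self) -> int:
        """Alignment length N: duplex pairs plus the central pair."""
        return len(self.duplex_pairs) + 1

    @property
    def average_duplex_rmsd(self) -> float:
        if not self.duplex_pairs:
            return 0.0
        return self.total_cost / len(self.duplex_pairs)


@dataclass(frozen=True)
class ComparisonResult:
    similar: bool
    algorithm_id: int
    alignment: Optional[Alignment] = None
    element_ratio_achieved: float = 0.0
    residue_ratio_achieved: float = 0.0
    rejection_reason: Optional[Rejection] = None
    k_used: Optional[int] = None


# ---------------------------------------------------------------------------
# stages

def precheck(
    desc_a: Descriptor, desc_b: Descriptor, params: ComparisonParams
) -> Optional[Rejection]:
    """Conditions checkable before the assignment stage; ``None`` = pass."""
    if desc_a.element_size != desc_b.element_size:
        raise ValueError(
            "descriptors can be structurally compared only if both were "
            f"built with the same element size ({desc_a.element_size} vs "
            f"{desc_b.element_size})"
        )
    size_a, size_b = desc_a.element_count, desc_b.element_count
    # 4/5|B| <= |A| <= 5/4|B|, checked in exact integer arithmetic
    if 4 * size_b > 5 * size_a or 4 * size_a > 5 * size_b:
        return Rejection.CARDINALITY
    kinds = desc_a.representative_atom_kinds
    pa = representative_atoms(desc_a.central_element.residues, kinds)
    pb = representative_atoms(desc_b.central_element.residues, kinds)
    if rmsd_guarded(pa, pb, params.big) > params.central_rmsd_max:
        return Rejection.CENTRAL
    return None


def build_cost_matrix(
    duplexes_a: Sequence[Duplex],
    duplexes_b: Sequence[Duplex],
    params: ComparisonParams,
) -> CostMatrix:
    """Duplex-pair RMSD cost matrix with sentinel for incomparable pairs.

    A pair of duplexes with different residue counts cannot be compared
    by RMSD and gets the sentinel; so does any pair above the per-pair
    RMSD ceiling (such a pair could never join a feasible alignment).
    """
    n, m = len(duplexes_a), len(duplexes_b)
    costs = np.full((n, m), params.big, dtype=float)
    for i, da in enumerate(duplexes_a):
        for j, db in enumerate(duplexes_b):
            c = rmsd_guarded(da.atoms, db.atoms, params.big)
            if c <= params.pair_rmsd_max:
                costs[i, j] = c
    return CostMatrix(costs=costs, big=params.big)


def _merged_sides(
    pairs: Sequence[tuple],
    desc_a: Descriptor,
    desc_b: Descriptor,
) -> tuple:
    els_a: list[Element] = [desc_a.central_element]
    els_b: list[Element] = [desc_b.central_element]
    for i, j in pairs:
        els_a.append(desc_a.other_elements[i])
        els_b.append(desc_b.other_elements[j])
    return _union_residues(els_a), _union_residues(els_b)


def finalize(
    candidate: AssignmentSolution,
    desc_a: Descriptor,
    desc_b: Descriptor,
    matrix: CostMatrix,
    params: ComparisonParams,
):
    """Turn an assignment candidate into an accepted :class:`Alignment`.

    Returns the alignment, or the :class:`Rejection` explaining why the
    candidate fails the remaining similarity conditions (equal merged
    residue counts, global RMSD, element and residue coverage).
    """
    side_a, side_b = _merged_sides(candidate.pairs, desc_a, desc_b)
    if len(side_a) != len(side_b):
        return Rejection.ATOM_COUNT
    n_aligned = candidate.size + 1
    size_a, size_b = desc_a.element_count, desc_b.element_count
    eps = 1e-9  # coverage bounds are inclusive at exact fractions
    if (
        n_aligned < params.element_ratio * size_a - eps
        or n_aligned < params.element_ratio * size_b - eps
    ):
        return Rejection.ELEMENT_RATIO
    if (
        len(side_a) < params.residue_ratio * desc_a.residue_count - eps
        or len(side_b) < params.residue_ratio * desc_b.residue_count - eps
    ):
        return Rejection.RESIDUE_RATIO
    kinds = desc_a.representative_atom_kinds
    pa = representative_atoms(side_a, kinds)
    pb = representative_atoms(side_b, kinds)
    sup = superpose(pa, pb)
    if sup.rmsd > params.global_rmsd_max:
        return Rejection.GLOBAL_RMSD
    return Alignment(
        duplex_pairs=tuple(candidate.pairs),
        residue_map=tuple((a.rid, b.rid) for a, b in zip(side_a, side_b)),
        total_cost=candidate.total_cost,
        global_rmsd=sup.rmsd,
        aligned_residue_counts=(len(side_a), len(side_b)),
    )


# ---------------------------------------------------------------------------
# shared comparison context

@dataclass
class _Context:
    desc_a: Descriptor
    desc_b: Descriptor
    params: ComparisonParams
    matrix: CostMatrix = field(init=False)
    duplexes_a: list = field(init=False)
    duplexes_b: list = field(init=False)

    def __post_init__(self):
        self.duplexes_a = make_duplexes(self.desc_a)
        self.duplexes_b = make_duplexes(self.desc_b)
        self.matrix = build_cost_matrix(
            self.duplexes_a, self.duplexes_b, self.params
        )

    @property
    def ks(self) -> list[int]:
        if self.desc_a.n < 1 or self.desc_b.n < 1:
            return []
        return asg.k_range(self.desc_a.n, self.desc_b.n)

    @property
    def kmin(self) -> int:
        return asg.k_min(self.desc_a.n, self.desc_b.n)

    def finalize(self, candidate: AssignmentSolution):
        return finalize(candidate, self.desc_a, self.desc_b, self.matrix, self.params)

    def result(
        self,
        algorithm_id: int,
        alignment,
        reason: Optional[Rejection],
        k_used: Optional[int] = None,
    ) -> ComparisonResult:
        if isinstance(alignment, Alignment):
            size_a, size_b = self.desc_a.element_count, self.desc_b.element_count
            el_ratio = min(
                alignment.n_aligned / size_a, alignment.n_aligned / size_b
            )
            res_ratio = min(
                alignment.aligned_residue_counts[0] / self.desc_a.residue_count,
                alignment.aligned_residue_counts[1] / self.desc_b.residue_count,
            )
            return ComparisonResult(
                similar=True,
                algorithm_id=algorithm_id,
                alignment=alignment,
                element_ratio_achieved=el_ratio,
                residue_ratio_achieved=res_ratio,
                k_used=k_used,
            )
        return ComparisonResult(
            similar=False,
            algorithm_id=algorithm_id,
            rejection_reason=reason,
        )


def _candidate_sort_key(ctx: _Context, alignment: Alignment) -> tuple:
    """Larger is better: duplex count, then aligned residues."""
    return (len(alignment.duplex_pairs), alignment.aligned_residue_counts[0])


def _select_best(ctx: _Context, accepted: list) -> Optional[Alignment]:
    best = None
    best_key = None
    for al in accepted:
        key = _candidate_sort_key(ctx, al)
        if best is None or key > best_key:
            best, best_key = al, key
    return best


# ---------------------------------------------------------------------------
# the four algorithms

def algorithm1(
    desc_a: Descriptor, desc_b: Descriptor, params: ComparisonParams
) -> ComparisonResult:
    """First-feasible strategy.

    ``K`` decreases from ``min(n, m)``; the first MA-feasible solution
    (including one salvaged by sub-solution extraction from a solution
    spoiled only by sentinel cells) is final: it is checked against the
    remaining similarity conditions once, and no further ``K`` is tried.
    """
    reason = precheck(desc_a, desc_b, params)
    ctx = _Context(desc_a, desc_b, params)
    if reason is not None:
        return ctx.result(1, None, reason)
    if not ctx.ks:
        return ctx.result(1, None, Rejection.NO_K)
    last_reason = Rejection.COST_LIMIT
    for k in ctx.ks:
        raw = asg._raw_k_solution(ctx.matrix, k)
        candidate = None
        if asg.ma_feasible(ctx.matrix, raw, params.f):
            candidate = raw
        else:
            candidate = asg.extract_subsolution(
                raw, ctx.matrix, params.f, minimum_size=ctx.kmin
            )
        if candidate is not None:
            outcome = ctx.finalize(candidate)
            if isinstance(outcome, Alignment):
                return ctx.result(1, outcome, None, k_used=candidate.size)
            return ctx.result(1, None, outcome)
    return ctx.result(1, None, last_reason)


def algorithm2(
    desc_a: Descriptor, desc_b: Descriptor, params: ComparisonParams
) -> ComparisonResult:
    """All-K strategy: one candidate per admissible ``K``, best accepted
    alignment chosen by duplex count, ties by aligned residue count."""
    reason = precheck(desc_a, desc_b, params)
    ctx = _Context(desc_a, desc_b, params)
    if reason is not None:
        return ctx.result(2, None, reason)
    if not ctx.ks:
        return ctx.result(2, None, Rejection.NO_K)
    accepted, last_reason = _collect_full_solutions(ctx)
    best = _select_best(ctx, accepted)
    if best is None:
        return ctx.result(2, None, last_reason)
    return ctx.result(2, best, None, k_used=len(best.duplex_pairs))


def _collect_full_solutions(ctx: _Context) -> tuple:
    accepted: list[Alignment] = []
    last_reason = Rejection.COST_LIMIT
    for k in ctx.ks:
        sol = asg.solve_ma(ctx.matrix, k, ctx.params.f)
        if sol is None:
            continue
        outcome = ctx.finalize(sol)
        if isinstance(outcome, Alignment):
            accepted.append(outcome)
        else:
            last_reason = outcome
    return accepted, last_reason


def algorithm3(
    desc_a: Descriptor, desc_b: Descriptor, params: ComparisonParams
) -> ComparisonResult:
    """All-K with partial solutions.

    For each ``K`` the assignment solution's pairs are sorted by cost;
    every sufficiently long prefix spawns a partial solution built by
    adding pairs one by one, skipping any pair that would leave the two
    merged substructures with unequal residue counts.  Partials within
    the cost limit and size bound compete with the full solutions.
    """
    reason = precheck(desc_a, desc_b, params)
    ctx = _Context(desc_a, desc_b, params)
    if reason is not None:
        return ctx.result(3, None, reason)
    if not ctx.ks:
        return ctx.result(3, None, Rejection.NO_K)
    accepted, last_reason = _collect_full_solutions(ctx)
    seen: set = {al.duplex_pairs for al in accepted}
    for k in ctx.ks:
        raw = asg._raw_k_solution(ctx.matrix, k)
        for partial in _partial_solutions(ctx, raw):
            if partial.pairs in seen:
                continue
            seen.add(partial.pairs)
            outcome = ctx.finalize(partial)
            if isinstance(outcome, Alignment):
                accepted.append(outcome)
            else:
                last_reason = outcome
    best = _select_best(ctx, accepted)
    if best is None:
        return ctx.result(3, None, last_reason)
    return ctx.result(3, best, None, k_used=len(best.duplex_pairs))


def _partial_solutions(ctx: _Context, raw: AssignmentSolution):
    """Feasible partial solutions from cost-sorted prefixes of ``raw``."""
    costs = ctx.matrix.costs
    ordered = sorted(raw.pairs, key=lambda p: (costs[p[0], p[1]], p))
    kmin = max(ctx.kmin, 1)
    emitted: set = set()
    for prefix_len in range(kmin, len(ordered) + 1):
        chosen: list[tuple] = []
        for pair in ordered[:prefix_len]:
            trial = chosen + [pair]
            side_a, side_b = _merged_sides(trial, ctx.desc_a, ctx.desc_b)
            if len(side_a) == len(side_b):
                chosen.append(pair)
        if len(chosen) < kmin:
            continue
        key = tuple(sorted(chosen))
        if key in emitted:
            continue
        emitted.add(key)
        total = float(sum(costs[i, j] for i, j in chosen))
        candidate = AssignmentSolution(pairs=tuple(chosen), total_cost=total)
        if asg.ma_feasible(ctx.matrix, candidate, ctx.params.f):
            yield candidate


def algorithm4(
    desc_a: Descriptor, desc_b: Descriptor, params: ComparisonParams
) -> ComparisonResult:
    """Exact backtracking over all duplex injections.

    Explores every partial injection of A's duplexes into B's restricted
    to comparable pairs (RMSD <= 3.5), checks each candidate of
    admissible size against all similarity conditions, and selects by
    duplex count, then aligned residue count, then average duplex RMSD
    (the order of the last two is configurable).  Branches that cannot
    reach the incumbent's duplex count are pruned, which never discards
    a potentially winning candidate.
    """
    reason = precheck(desc_a, desc_b, params)
    ctx = _Context(desc_a, desc_b, params)
    if reason is not None:
        return ctx.result(4, None, reason)
    n, m = ctx.matrix.n, ctx.matrix.m
    if n < 1 or m < 1:
        return ctx.result(4, None, Rejection.NO_K)
    kmin = max(ctx.kmin, 1)
    if kmin > min(n, m):
        return ctx.result(4, None, Rejection.NO_K)
    costs = ctx.matrix.costs
    feasible_cols = [
        [j for j in range(m) if costs[i, j] < ctx.params.big] for i in range(n)
    ]
    # fail-first: rows with few comparable partners early
    row_order = sorted(range(n), key=lambda i: (len(feasible_cols[i]), i))

    best: dict = {"alignment": None, "key": None, "reason": Rejection.COST_LIMIT}

    def candidate_key(al: Alignment) -> tuple:
        if ctx.params.tiebreak_residues_first:
            return (
                len(al.duplex_pairs),
                al.aligned_residue_counts[0],
                -al.average_duplex_rmsd,
            )
        return (
            len(al.duplex_pairs),
            -al.average_duplex_rmsd,
            al.aligned_residue_counts[0],
        )

    def consider(pairs: list):
        size = len(pairs)
        if size < kmin:
            return
        inc = best["alignment"]
        if inc is not None and size < len(inc.duplex_pairs):
            return
        total = float(sum(costs[i, j] for i, j in pairs))
        candidate = AssignmentSolution(pairs=tuple(pairs), total_cost=total)
        outcome = ctx.finalize(candidate)
        if isinstance(outcome, Alignment):
            key = candidate_key(outcome)
            if best["key"] is None or key > best["key"]:
                best["alignment"], best["key"] = outcome, key
        else:
            best["reason"] = outcome

    used = [False] * m

    def dfs(pos: int, pairs: list):
        if pos == len(row_order):
            consider(pairs)
            return
        remaining = len(row_order) - pos
        inc = best["alignment"]
        floor = kmin if inc is None else max(kmin, len(inc.duplex_pairs))
        if len(pairs) + remaining < floor:
            return
        i = row_order[pos]
        for j in feasible_cols[i]:
            if used[j]:
                continue
            used[j] = True
            pairs.append((i, j))
            dfs(pos + 1, pairs)
            pairs.pop()
            used[j] = False
        dfs(pos + 1, pairs)  # leave duplex i unaligned

    dfs(0, [])
    al = best["alignment"]
    if al is None:
        return ctx.result(4, None, best["reason"])
    return ctx.result(4, al, None, k_used=len(al.duplex_pairs))


_ALGORITHMS = {1: algorithm1, 2: algorithm2, 3: algorithm3, 4: algorithm4}


# ---------------------------------------------------------------------------
# symmetric entry point

def _descriptor_key(desc: Descriptor) -> tuple:
    coords = representative_atoms(desc.residue_set, desc.representative_atom_kinds)
    return (
        desc.n,
        desc.residue_count,
        desc.name,
        np.round(coords, 3).tobytes(),
    )


def _swap_result(result: ComparisonResult) -> ComparisonResult:
    if result.alignment is None:
        return result
    al = result.alignment
    swapped = Alignment(
        duplex_pairs=tuple(sorted((j, i) for i, j in al.duplex_pairs)),
        residue_map=tuple((b, a) for a, b in al.residue_map),
        total_cost=al.total_cost,
        global_rmsd=al.global_rmsd,
        aligned_residue_counts=(al.aligned_residue_counts[1], al.aligned_residue_counts[0]),
    )
    return replace(result, alignment=swapped)


def compare(
    desc_a: Descriptor,
    desc_b: Descriptor,
    algorithm_id: int = 3,
    params: Optional[ComparisonParams] = None,
) -> ComparisonResult:
    """Compare two descriptors and classify them as similar or not.

    Matching A to B gives the same result as matching B to A: the two
    descriptors are brought into a canonical order before the (otherwise
    direction-dependent in its tie-breaking) search runs, and the
    answer is mapped back to the caller's order.
    """
    if algorithm_id not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm id {algorithm_id}; use 1-4")
    if params is None:
        params = ComparisonParams()
    if _descriptor_key(desc_b) < _descriptor_key(desc_a):
        return _swap_result(
            _ALGORITHMS[algorithm_id](desc_b, desc_a, params)
        )
    return _ALGORITHMS[algorithm_id](desc_a, desc_b, params)


# ---------------------------------------------------------------------------
# aligned output structures

def superposed_structures(
    desc_a: Descriptor, desc_b: Descriptor, alignment: Alignment
) -> tuple:
    """The two aligned substructures, B rigidly moved onto A.

    Returns two :class:`Structure` objects covering the descriptors'
    full residue sets, the second transformed by the optimal
    superposition of the aligned representative atoms.
    """
    kinds = desc_a.representative_atom_kinds
    map_a = {rid_a for rid_a, _ in alignment.residue_map}
    map_b = {rid_b for _, rid_b in alignment.residue_map}
    res_a = [r for r in desc_a.residue_set if r.rid in map_a]
    res_b_lookup = {r.rid: r for r in desc_b.residue_set}
    res_b = [res_b_lookup[rid_b] for _, rid_b in alignment.residue_map]
    sup = superpose(
        representative_atoms(res_a, kinds), representative_atoms(res_b, kinds)
    )

    def to_structure(desc: Descriptor, transform) -> Structure:
        chains: dict[str, list] = {}
        for r in desc.residue_set:
            atoms = tuple(
                replace(a, position=transform(a.position)) for a in r.atoms
            )
            chains.setdefault(r.chain_id, []).append(replace(r, atoms=atoms))
        return Structure(
            id=desc.name,
            chains={c: tuple(rs) for c, rs in chains.items()},
        )

    ident = lambda p: p
    moved = lambda p: sup.rotation @ p + sup.translation
    return to_structure(desc_a, ident), to_structure(desc_b, moved)
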