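"""The maximum-size assignment (MA) core.

The greatest structural alignment of two descriptors reduces to the
following combinatorial problem: given an ``n x m`` cost matrix of duplex
pair RMSD values, select as many cells as possible, at most one per row
and per column, with total cost at most ``L``.  This module provides

* :func:`k_range` — the admissible assignment sizes ``K`` implied by the
  element-coverage requirement (at least 4/5 of either descriptor);
* :func:`to_square` — the polynomial transformation of a size-``K`` MA
  instance into a classic square assignment instance (pad with zero
  rows/columns and one all-``M`` corner block);
* :func:`solve_square` — a minimum-cost perfect assignment solver with a
  deterministic lexicographic tie-break;
* :func:`solve_ma` — the composition: cheapest size-``K`` assignment,
  accepted only if it uses no sentinel cell and stays within ``L = f*K``;
* :func:`extract_subsolution` — the shortcut that salvages a feasible
  smaller assignment from an infeasible one whose only defects are
  selected sentinel cells.

Costs are RMSD values rounded to 2 decimals, hence exactly representable
once scaled by 100; all feasibility arithmetic is done on scaled integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import M_SENTINEL

_SCALE = 100  # costs have exactly 2 decimals


@dataclass(frozen=True)
class CostMatrix:
    """An ``n x m`` matrix of duplex-pair alignment costs.

    Finite entries are RMSD values (2 decimals, <= the per-pair RMSD
    ceiling); incomparable or over-threshold pairs carry the sentinel
    ``M``.  Rows index the duplexes of descriptor A, columns those of B.
    """

    costs: np.ndarray
    big: float = M_SENTINEL

    def __post_init__(self):
        arr = np.asarray(self.costs, dtype=float)
        if arr.ndim != 2:
            raise ValueError("cost matrix must be 2-dimensional")
        if arr.size and (arr < 0).any():
            raise ValueError("costs must be non-negative")
        object.__setattr__(self, "costs", arr)

    @property
    def n(self) -> int:
        return self.costs.shape[0]

    @property
    def m(self) -> int:
        return self.costs.shape[1]

    def is_sentinel(self, i: int, j: int) -> bool:
        return self.costs[i, j] >= self.big

    def scaled(self) -> np.ndarray:
        """Integer cost matrix (costs * 100, sentinel mapped exactly)."""
        out = np.rint(self.costs * _SCALE).astype(np.int64)
        out[self.costs >= self.big] = int(self.big) * _SCALE
        return out


@dataclass(frozen=True)
class SquareInstance:
    """A square assignment instance produced by :func:`to_square`.

    ``n_a = n + m - K``.  The top-left ``n x m`` block holds the original
    costs, the added right columns and bottom rows are zero, and the
    bottom-right ``(m-K) x (n-K)`` block is all ``M`` — forcing every
    padding row/column to bind an original one.
    """

    matrix: np.ndarray
    n: int
    m: int
    k: int
    big: float = M_SENTINEL

    @property
    def n_a(self) -> int:
        return self.matrix.shape[0]

    def is_original(self, i: int, j: int) -> bool:
        return i < self.n and j < self.m


@dataclass(frozen=True)
class AssignmentSolution:
    """A partial assignment: selected (row, column) pairs and their cost."""

    pairs: tuple
    total_cost: float

    @property
    def size(self) -> int:
        return len(self.pairs)

    def __post_init__(self):
        rows = [i for i, _ in self.pairs]
        cols = [j for _, j in self.pairs]
        if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
            raise ValueError("assignment reuses a row or column")
        object.__setattr__(self, "pairs", tuple(sorted(self.pairs)))


def k_range(n: int, m: int) -> list[int]:
    """Admissible assignment sizes, largest first.

    ``K`` runs from ``min(n, m)`` down to
    ``ceil(4/5 * (max(n, m) + 1)) - 1``, the smallest size whose alignment
    length ``N = K + 1`` still covers at least 4/5 of the larger
    descriptor.  The list is empty when even the full matching is too
    small to satisfy the coverage bound.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    k_max = min(n, m)
    k_min = math.ceil(4 * (max(n, m) + 1) / 5) - 1
    if k_min > k_max:
        return []
    return list(range(k_max, k_min - 1, -1))


def k_min(n: int, m: int) -> int:
    """Lower endpoint of the admissible ``K`` interval (may exceed min(n, m))."""
    return math.ceil(4 * (max(n, m) + 1) / 5) - 1


def to_square(matrix: CostMatrix, k: int) -> SquareInstance:
    """Transform a size-``k`` MA instance into a square assignment instance.

    Appends ``n - k`` zero columns and ``m - k`` zero rows; the block at
    their intersection is filled with the sentinel so that padding rows
    can only consume padding columns up to the allowed slack.  For
    ``k = n = m`` the matrix is returned unchanged.
    """
    n, m = matrix.n, matrix.m
    if k > min(n, m):
        raise ValueError(f"K={k} exceeds min(n, m)={min(n, m)}")
    if k < 0:
        raise ValueError("K must be non-negative")
    n_a = n + m - k
    sq = np.zeros((n_a, n_a), dtype=float)
    sq[:n, :m] = matrix.costs
    if m > k and n > k:
        sq[n:, m:] = matrix.big
    return SquareInstance(matrix=sq, n=n, m=m, k=k, big=matrix.big)


def _scaled_square(instance: SquareInstance) -> np.ndarray:
    out = np.rint(instance.matrix * _SCALE).astype(np.int64)
    out[instance.matrix >= instance.big] = int(instance.big) * _SCALE
    return out


def solve_square(instance: SquareInstance) -> AssignmentSolution:
    """Minimum-cost perfect assignment on a square instance.

    The Hungarian-method optimum is computed by
    :func:`scipy.optimize.linear_sum_assignment`; among cost-equal optima
    the lexicographically smallest pair set (row-major) is returned, made
    canonical by fixing, row by row, the smallest column that still
    admits an optimal completion.
    """
    c = _scaled_square(instance)
    n_a = c.shape[0]
    if n_a == 0:
        return AssignmentSolution(pairs=(), total_cost=0.0)
    rows, cols = linear_sum_assignment(c)
    best = int(c[rows, cols].sum())

    chosen: list[int] = []
    free_cols = list(range(n_a))
    prefix_cost = 0
    for i in range(n_a):
        # default candidate from a fresh solve keeps this O(n^2) calls worst case
        for j in sorted(free_cols):
            rest_rows = np.arange(i + 1, n_a)
            rest_cols = np.array([cc for cc in free_cols if cc != j], dtype=int)
            sub_cost = 0
            if rest_rows.size:
                sub = c[np.ix_(rest_rows, rest_cols)]
                rr, cc_idx = linear_sum_assignment(sub)
                sub_cost = int(sub[rr, cc_idx].sum())
            if prefix_cost + int(c[i, j]) + sub_cost == best:
                chosen.append(j)
                prefix_cost += int(c[i, j])
                free_cols.remove(j)
                break
        else:  # pragma: no cover - optimal completion always exists
            raise RuntimeError("no optimal completion found")
    pairs = tuple((i, j) for i, j in enumerate(chosen))
    return AssignmentSolution(pairs=pairs, total_cost=best / _SCALE)


def _raw_k_solution(matrix: CostMatrix, k: int) -> AssignmentSolution:
    """Cheapest size-``k`` assignment, sentinel cells permitted.

    Solves the transformed square instance and strips the padding pairs;
    exactly ``k`` pairs inside the original block remain.
    """
    instance = to_square(matrix, k)
    full = solve_square(instance)
    real = tuple((i, j) for i, j in full.pairs if instance.is_original(i, j))
    cost = float(sum(matrix.costs[i, j] for i, j in real))
    return AssignmentSolution(pairs=real, total_cost=cost)


def ma_feasible(matrix: CostMatrix, solution: AssignmentSolution, f: float) -> bool:
    """Does ``solution`` satisfy the MA constraints for limit ``L = f*size``?

    Checked on scaled integers: no sentinel cell selected and total scaled
    cost at most ``round(100 * f * size)``.
    """
    if any(matrix.is_sentinel(i, j) for i, j in solution.pairs):
        return False
    scaled_total = int(round(solution.total_cost * _SCALE))
    limit = int(round(f * solution.size * _SCALE))
    return scaled_total <= limit


def solve_ma(matrix: CostMatrix, k: int, f: float) -> Optional[AssignmentSolution]:
    """Cheapest size-``k`` assignment if it is MA-feasible, else ``None``.

    Feasibility means: none of the ``k`` selected cells is the sentinel
    and the total cost does not exceed ``L = f * k``.  Because the square
    solver minimises total cost, a returned solution is the cheapest
    size-``k`` assignment overall.
    """
    if k not in k_range(matrix.n, matrix.m):
        raise ValueError(f"K={k} is not admissible for n={matrix.n}, m={matrix.m}")
    raw = _raw_k_solution(matrix, k)
    if ma_feasible(matrix, raw, f):
        return raw
    return None


def extract_subsolution(
    solution: AssignmentSolution,
    matrix: CostMatrix,
    f: float,
    minimum_size: Optional[int] = None,
) -> Optional[AssignmentSolution]:
    """Salvage a feasible smaller assignment from an infeasible one.

    Applicable only when the infeasible solution consists of regular-cost
    pairs plus at least one sentinel pair and nothing else; the regular
    pairs then form a candidate of size ``K' = #regular``, accepted if
    ``K'`` still meets the admissible lower bound and its cost is within
    ``f * K'``.
    """
    sentinel = [(i, j) for i, j in solution.pairs if matrix.is_sentinel(i, j)]
    if not sentinel:
        return None  # rule only applies to solutions spoiled by sentinel cells
    regular = tuple((i, j) for i, j in solution.pairs if not matrix.is_sentinel(i, j))
    if minimum_size is None:
        minimum_size = k_min(matrix.n, matrix.m)
    if len(regular) < max(minimum_size, 1):
        return None
    cost = float(sum(matrix.costs[i, j] for i, j in regular))
    candidate = AssignmentSolution(pairs=regular, total_cost=cost)
    if not ma_feasible(matrix, candidate, f):
        return None
    return candidate


# ---------------------------------------------------------------------------
# Text (TSV) round-trip for cost matrices, used by tests and the CLI.

def write_cost_matrix(matrix: CostMatrix, path) -> None:
    """Write a cost matrix as tab-separated text with ``M`` sentinel tokens."""
    with open(path, "w") as fh:
        for row in matrix.costs:
            cells = ["M" if v >= matrix.big else f"{v:.2f}" for v in row]
            fh.write("\t".join(cells) + "\n")


def read_cost_matrix(path, big: float = M_SENTINEL) -> CostMatrix:
    """Read a tab-separated cost matrix; the token ``M`` marks sentinels."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = []
            for tok in line.split("\t"):
                tok = tok.strip()
                if tok.upper() == "M":
                    cells.append(big)
                else:
                    try:
                        cells.append(float(tok))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}: line {lineno}: bad cost token {tok!r}"
                        ) from exc
            rows.append(cells)
    if not rows:
        raise ValueError(f"{path}: empty cost matrix")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged cost matrix")
    return CostMatrix(costs=np.array(rows, dtype=float), big=big)
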