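"""The maximum-size assignment core on a bare cost matrix.

Draws a random 4 x 4 duplex-cost matrix (RMSD values on [0.5, 3.5],
one entry knocked out by the sentinel M), lists the admissible
assignment sizes K, and solves the maximum-size assignment for each K
via the padding transformation to the square assignment problem.  With
n = m = 4 the admissible K interval is {4, 3}: an alignment must cover
at least 4/5 of the larger descriptor's elements.
"""

import numpy as np

from descalign import generate_cost_matrix, k_range, solve_ma

matrix = generate_cost_matrix(4, 4, seed=42, m_fraction=0.1)
with np.printoptions(formatter={"float": lambda v: "   M" if v > 3.5 else f"{v:.2f}"}):
    print("cost matrix (duplex-pair RMSD, A):")
    print(matrix.costs)
print()
f = 2.33
for k in k_range(matrix.n, matrix.m):
    solution = solve_ma(matrix, k, f)
    limit = f * k
    if solution is None:
        print(f"K={k}: infeasible within L = f*K = {limit:.2f}")
    else:
        pairs = " ".join(f"({i},{j})" for i, j in solution.pairs)
        print(f"K={k}: cheapest assignment {pairs}, "
              f"total cost {solution.total_cost:.2f} <= L = {limit:.2f}")
print()
print("The K=4 row, when feasible, is the candidate the first-feasible")
print("algorithm would pass on to the global-RMSD verification stage.")
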