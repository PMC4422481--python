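"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle sums
exact hypergeometric probabilities with integer binomial coefficients, and
the segmentation oracle enumerates every breakpoint placement.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def fisher_greater_oracle(n_ref: int, n_alt: int, t_ref: int, t_alt: int
                          ) -> float:
    """One-sided p for tumor-alt enrichment on [[n_ref, n_alt],
    [t_ref, t_alt]]: the upper hypergeometric tail of the top-left cell
    given fixed margins, computed with exact integer arithmetic."""
    a = n_ref
    row1 = n_ref + n_alt
    col1 = n_ref + t_ref
    total = row1 + t_ref + t_alt
    amax = min(row1, col1)
    num = sum(comb(col1, x) * comb(total - col1, row1 - x)
              for x in range(a, amax + 1)
              if 0 <= row1 - x <= total - col1)
    den = comb(total, row1)
    return num / den


def _sse(prefix1: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    s = prefix1[j] - prefix1[i]
    return max(prefix2[j] - prefix2[i] - s * s / (j - i), 0.0)


def exhaustive_segmentation(y, penalty: float, max_breakpoints: int
                            ) -> tuple[float, tuple[int, ...]]:
    """Minimum of SSE + penalty * breakpoints over every placement of up to
    ``max_breakpoints`` breakpoints.  Returns (cost, breakpoint indices)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    p1 = np.concatenate(([0.0], np.cumsum(y)))
    p2 = np.concatenate(([0.0], np.cumsum(y * y)))
    best_cost = float("inf")
    best: tuple[int, ...] = ()
    for k in range(0, max_breakpoints + 1):
        for cuts in combinations(range(1, n), k):
            edges = (0, *cuts, n)
            cost = sum(_sse(p1, p2, i, j)
                       for i, j in zip(edges, edges[1:])) + penalty * k
            if cost < best_cost - 1e-12:
                best_cost = cost
                best = cuts
    return best_cost, best
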