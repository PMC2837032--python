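"""Independent arbitrary-precision oracles used only by the tests.

These deliberately avoid the library's scipy-based code paths: everything
here is exact integer/rational arithmetic, so oracle values carry no
floating-point error beyond the final log/float conversion.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb

import numpy as np


def exact_conditional_pmf(y: int, x: int, n1: int, n2: int) -> Fraction:
    """p(y|x) = (n2/n1)^y (x+y)!/(x!y!) / (1+n2/n1)^(x+y+1), exactly."""
    r = Fraction(n2, n1)
    return r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)


def exact_log_tail(x: int, y: int, n1: int, n2: int) -> float:
    """Natural log of the exact lower-tail sum Σ_{y'=0..y} p(y'|x).

    Over the common denominator (n1+n2)^(x+y+1) the numerator is a plain
    integer, so only one log conversion happens at the end.
    """
    s = n1 + n2
    num = sum(comb(x + yp, yp) * n2**yp * s ** (y - yp) for yp in range(y + 1))
    num *= n1 ** (x + 1)
    return math.log(num) - (x + y + 1) * math.log(s)


def exact_log_tail_grid(xmax: int, ymax: int, n1: int, n2: int) -> np.ndarray:
    """exact_log_tail over the full grid, via an O(1)-per-cell recurrence."""
    s = n1 + n2
    out = np.empty((xmax + 1, ymax + 1))
    for x in range(xmax + 1):
        scale = n1 ** (x + 1)
        binom = 1  # C(x+y, y)
        n2pow = 1  # n2^y
        num = scale
        out[x, 0] = math.log(num) - (x + 1) * math.log(s)
        for y in range(1, ymax + 1):
            binom = binom * (x + y) // y
            n2pow *= n2
            num = num * s + scale * binom * n2pow
            out[x, y] = math.log(num) - (x + y + 1) * math.log(s)
    return out


def exact_fisher_two_tailed(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-tailed Fisher exact p by exhaustive enumeration, exactly.

    Sums hypergeometric point probabilities <= the observed one within the
    1e-7 relative tolerance convention, all in integer arithmetic.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return Fraction(1)
    lo, hi = max(0, col1 - (n - row1)), min(col1, row1)
    nums = {k: comb(col1, k) * comb(n - col1, row1 - k) for k in range(lo, hi + 1)}
    den = comb(n, row1)
    obs = nums[a]
    tol_num, tol_den = 10**7 + 1, 10**7  # (1 + 1e-7) as a ratio
    total = sum(v for v in nums.values() if v * tol_den <= obs * tol_num)
    return min(Fraction(total, den), Fraction(1))


def stepup_fdr(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg by the textbook definition (suffix minimum)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj
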