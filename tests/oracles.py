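"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by direct enumeration with exact
rational arithmetic (or exhaustive search), independently of the package
code paths it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import factorial

import numpy as np


def hwe_exact_p_enumeration(n_gg: int, n_gc: int, n_cc: int) -> Fraction:
    """Exact HWE p by full enumeration of heterozygote counts.

    Conditional probability of h heterozygotes given n and the C-allele
    count, via factorials in exact rational arithmetic; p sums the
    probabilities of configurations no more likely than the observed one.
    """
    n = n_gg + n_gc + n_cc
    n_c = 2 * n_cc + n_gc
    n_g = 2 * n - n_c

    def prob(h: int) -> Fraction:
        c = (n_c - h) // 2
        g = (n_g - h) // 2
        num = Fraction(factorial(n) * 2**h * factorial(n_c) * factorial(n_g))
        den = Fraction(factorial(g) * factorial(h) * factorial(c) * factorial(2 * n))
        return num / den

    probs = {h: prob(h) for h in range(n_c % 2, min(n_c, n_g) + 1, 2)}
    p_obs = probs[n_gc]
    return sum(p for p in probs.values() if p <= p_obs)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating every table with the fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k: int) -> Fraction:
        # hypergeometric pmf via factorials
        a_, b_, c_, d_ = k, r1 - k, c1 - k, r2 - (c1 - k)
        num = Fraction(factorial(r1) * factorial(r2) * factorial(c1) * factorial(n - c1))
        den = Fraction(factorial(n) * factorial(a_) * factorial(b_) * factorial(c_) * factorial(d_))
        return num / den

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: prob(k) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def best_contiguous_three_partition(values: np.ndarray) -> tuple[float, list[np.ndarray]]:
    """Exhaustive search over contiguous 3-partitions of the sorted values.

    Returns the minimal total within-cluster SSE and the partition. The
    optimal 1-D k-means solution is contiguous on the sorted axis, so
    this is a ground-truth oracle for k=3 clustering.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best = (np.inf, None)
    for i, j in itertools.combinations(range(1, n), 2):
        parts = [x[:i], x[i:j], x[j:]]
        sse = sum(((p - p.mean()) ** 2).sum() for p in parts)
        if sse < best[0] - 1e-12:
            best = (sse, parts)
    return best


def anova_f_by_hand(groups: list[list[float]]) -> tuple[float, int, int]:
    """Textbook between/within sums-of-squares decomposition."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw
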