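"""Independent brute-force oracles used by the tests.

These deliberately avoid the recurrence/convolution code paths of the
package: K and X pmfs are computed by exhaustive enumeration over all
per-locus outcome patterns, sharing probabilities by closed forms, and the
Monte-Carlo HWE p-value by full multinomial enumeration.
"""

from __future__ import annotations

from itertools import product
from math import comb, factorial

import numpy as np


def enum_K_pmf(h: np.ndarray) -> np.ndarray:
    """P(K = r) by summing over all 2^m heterozygosity patterns."""
    h = np.asarray(h, dtype=float)
    m = len(h)
    pmf = np.zeros(m + 1)
    for pattern in product((0, 1), repeat=m):
        prob = np.prod([hm if z else 1.0 - hm for z, hm in zip(pattern, h)])
        pmf[sum(pattern)] += prob
    return pmf


def enum_X_pmf(probs: np.ndarray) -> np.ndarray:
    """P(X = r) by summing over all 3^m per-locus sharing patterns."""
    probs = np.asarray(probs, dtype=float)  # (m, 3)
    m = probs.shape[0]
    pmf = np.zeros(2 * m + 1)
    for pattern in product((0, 1, 2), repeat=m):
        prob = np.prod([probs[i, k] for i, k in enumerate(pattern)])
        pmf[sum(pattern)] += prob
    return pmf


def weir_share_closed_form(p: np.ndarray) -> tuple[float, float, float]:
    """(p0, p1, p2) for unrelated HWE pairs from closed-form sums."""
    p = np.asarray(p, dtype=float)
    p2 = float((p**4).sum())
    p0 = float((p**2 * (1 - p) ** 2).sum())
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            p2 += 4 * p[i] ** 2 * p[j] ** 2
            p0 += 2 * p[i] * p[j] * (1 - p[i] - p[j]) ** 2
    return p0, 1.0 - p0 - p2, p2


def multiset_shared(a: tuple[str, str], b: tuple[str, str]) -> int:
    """Multiset-intersection size by explicit element removal."""
    pool = list(b)
    count = 0
    for allele in a:
        if allele in pool:
            pool.remove(allele)
            count += 1
    return count


def exhaustive_multinomial_p(observed: np.ndarray, probs: np.ndarray) -> float:
    """Exact P(X^2 >= X^2_obs) under multinomial(n, probs), small n only."""
    observed = np.asarray(observed, dtype=float)
    probs = np.asarray(probs, dtype=float)
    n = int(observed.sum())
    e = n * probs
    x2_obs = (((observed - e) ** 2) / e).sum()
    total = 0.0
    k = len(probs)

    def tables(remaining: int, cats: int):
        if cats == 1:
            yield (remaining,)
            return
        for c in range(remaining + 1):
            for rest in tables(remaining - c, cats - 1):
                yield (c, *rest)

    for table in tables(n, k):
        o = np.array(table, dtype=float)
        x2 = (((o - e) ** 2) / e).sum()
        if x2 >= x2_obs - 1e-12:
            weight = factorial(n)
            for c, pc in zip(table, probs):
                weight = weight / factorial(c) * pc**c
            total += weight
    return total
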