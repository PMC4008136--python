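"""Independent reference implementations used only to check the package.

Everything here is written from the definitions with the standard
library (Fractions, math, statistics) so it shares no code path with
the implementation under test.
"""

from __future__ import annotations

import math
import statistics
from fractions import Fraction


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins.

    Sums the exact (rational) hypergeometric point masses of every table
    with the observed margins whose mass does not exceed the observed
    table's mass.
    """
    r1, n = a + b, a + b + c + d
    k = a + c
    denom = math.comb(n, r1)

    def pmf(x: int) -> Fraction:
        return Fraction(math.comb(k, x) * math.comb(n - k, r1 - x), denom)

    obs = pmf(a)
    lo, hi = max(0, k - (c + d)), min(k, r1)
    return float(sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= obs))


def qdmr_stack(levels, eps: float = 1e-4, c: float = 5.0,
               eps_t: float = 1e-4) -> dict:
    """H0, T_br, H_P, w_r, H_Q from the printed formulas, step by step."""
    m = list(map(float, levels))
    n = len(m)

    def entropy(vals):
        tot = sum(vals)
        if tot == 0:
            return math.log2(n)
        h = 0.0
        for v in vals:
            p = v / tot
            if p > 0:
                h -= p * math.log2(p)
        return h

    med = statistics.median(m)
    mad = statistics.median(abs(x - med) for x in m)
    num = den = 0.0
    for x in m:
        u = (x - med) / (c * mad + eps_t)
        w = (1 - u * u) ** 2 if abs(u) < 1 else 0.0
        num += w * x
        den += w
    t_br = num / den
    dist = [abs(x - t_br) for x in m]
    w_r = abs(math.log2((max(m) - min(m)) + eps))
    if sum(dist) == 0:
        h_q = math.inf
        h_p = math.nan
    else:
        h_p = entropy(dist)
        h_q = h_p * w_r
    return {"H0": entropy(m), "T_br": t_br, "H_P": h_p,
            "w_r": w_r, "H_Q": h_q}


def hypergeom_upper_tail(k: int, n_pop: int, n_success: int,
                         n_draw: int) -> float:
    """P(X >= k) for a hypergeometric draw, by exact rational summation."""
    denom = math.comb(n_pop, n_draw)
    hi = min(n_success, n_draw)
    return float(sum(
        Fraction(math.comb(n_success, x)
                 * math.comb(n_pop - n_success, n_draw - x), denom)
        for x in range(k, hi + 1)))


def poisson_binomial_pmf(probs) -> list:
    """PMF of a sum of independent Bernoulli(p_i), by convolution."""
    pmf = [1.0]
    for p in probs:
        nxt = [0.0] * (len(pmf) + 1)
        for k, q in enumerate(pmf):
            nxt[k] += q * (1 - p)
            nxt[k + 1] += q * p
        pmf = nxt
    return pmf
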