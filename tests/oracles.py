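"""Brute-force enumeration oracles for the exact tests.

These are deliberately naive and independent of the implementations they
check: hypergeometric enumeration for Fisher's test, full outcome
enumeration for the binomial test, sign-assignment enumeration for the
Wilcoxon signed-rank test, and the literal step-up definition for BH.
"""

from itertools import product
from math import comb

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Sum hypergeometric probabilities <= that of the observed table
    over all tables with the same margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # table [[x, r1-x], [c1-x, r2-(c1-x)]]
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return min(1.0, sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12)))


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Minimum-likelihood two-sided binomial p by full outcome enumeration."""
    pmf = [comb(n, x) * p0**x * (1 - p0) ** (n - x) for x in range(n + 1)]
    p_obs = pmf[k]
    return min(1.0, sum(px for px in pmf if px <= p_obs * (1 + 1e-12)))


def signed_rank_two_sided(diffs) -> float:
    """Exact signed-rank p by enumerating all 2^n sign assignments.

    Two-sided as min(1, 2 * min(P(W <= w), P(W >= w))), matching the
    standard exact convention. Assumes no zeros and no tied |diffs|.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = (ws <= w_obs).mean()
    p_ge = (ws >= w_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


def bh_step_up(p) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
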