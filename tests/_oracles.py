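"""Independent brute-force oracles shared by the statistics tests.

Each function re-derives a statistic from its definition (literal step-up,
exhaustive enumeration) without touching the library implementations.
"""

import itertools

import numpy as np


def bh_brute_force(pvals):
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        q[idx] = min(
            min(1.0, m * p[order[j]] / (j + 1))
            for j in range(rank_pos, m))
    return q


def wilcoxon_enumeration(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Assumes tie-free nonzero |differences| (distinct ranks).
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2 ** n


def mannwhitney_enumeration(a, b):
    """Exact two-sided rank-sum p by enumerating all group labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = a.size, b.size
    mu = n * m / 2.0
    ranks = np.argsort(np.argsort(pooled)) + 1.0

    def u_of(idx_a):
        r_a = ranks[list(idx_a)].sum()
        return r_a - n * (n + 1) / 2.0

    u_obs = u_of(range(n))
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = u_of(combo)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total
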