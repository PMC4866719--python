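"""Independent oracles for the exact R x 2 test, shared across test modules.

Both oracles enumerate every margin-consistent table directly and share no
code with the split-half engine beyond the definition of the statistic.
"""

import math

import numpy as np
from scipy.special import gammaln

from mitocomp.exact_tests import TIE_REL


def oracle_int(rows):
    """Naive recursive enumeration in exact integer arithmetic."""
    c1 = sum(a for a, _ in rows)
    num_obs = math.prod(math.comb(a + b, a) for a, b in rows)
    r = [a + b for a, b in rows]
    acc = 0

    def rec(k, s, num):
        nonlocal acc
        if k == len(r):
            if s == 0 and num <= num_obs + num_obs * TIE_REL:
                acc += num
            return
        rest = sum(r[k + 1:])
        for a in range(max(0, s - rest), min(r[k], s) + 1):
            rec(k + 1, s - a, num * math.comb(r[k], a))

    rec(0, c1, 1)
    return acc / math.comb(sum(r), c1)


def oracle_grid(rows):
    """Vectorized full-grid enumeration: all tables materialized at once."""
    r = np.array([a + b for a, b in rows])
    c1 = int(sum(a for a, _ in rows))
    grids = np.meshgrid(*[np.arange(ri + 1) for ri in r[:-1]], indexing="ij")
    a_last = c1 - sum(g for g in grids)
    feasible = (a_last >= 0) & (a_last <= r[-1])

    def lc(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    logw = np.zeros(grids[0].shape)
    for g, ri in zip(grids, r[:-1]):
        logw = logw + lc(ri, g)
    logw = logw + np.where(feasible, lc(r[-1], np.clip(a_last, 0, r[-1])), -np.inf)
    l_obs = float(sum(lc(ri, a) for (a, _), ri in zip(rows, r)))
    w = np.exp(logw[feasible])
    total = math.comb(int(r.sum()), c1)
    return float(w[logw[feasible] <= l_obs + math.log1p(TIE_REL)].sum()) / total


def random_table(rng, max_r=4, max_cell=10):
    while True:
        R = int(rng.integers(2, max_r + 1))
        rows = [
            (int(rng.integers(0, max_cell + 1)), int(rng.integers(0, max_cell + 1)))
            for _ in range(R)
        ]
        if (
            sum(a for a, _ in rows)
            and sum(b for _, b in rows)
            and all(a + b > 0 for a, b in rows)
        ):
            return rows
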