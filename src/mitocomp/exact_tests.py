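"""Exact conditional tests for R x 2 contingency tables.

The central statistic is the two-sided Fisher exact test under the
probability-ordering criterion: conditioning on all margins, the null
probability of a table with row totals r_i, first-column entries a_i and
first-column total c1 is

    P(a) = prod_i C(r_i, a_i) / C(N, c1),

and the p-value sums P over every margin-consistent table whose probability
does not exceed the observed one (with a small relative tie tolerance, as is
conventional for exact tests on floating-point probabilities).

The enumeration is exact but implicit: rows are split into a "left" half,
materialized as per-row-sum arrays of log-probabilities sorted with running
cumulative masses, and a "right" half that is streamed; each right-hand
partial table is resolved against the left half with a single binary search.
Every margin-consistent table is therefore counted exactly once without ever
being visited individually, which keeps tables as large as 9 x 2 with
N ~ 700 in the range of seconds to a couple of minutes. No Monte Carlo, no
truncation; the only inexactness is float64 rounding (~1e-13 relative).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import kruskal as _scipy_kruskal

# relative tie tolerance: tables with P <= P_obs * (1 + TIE_REL) are counted
TIE_REL = 1e-7


def _pin_mmap_threshold() -> None:
    """Keep glibc's mmap threshold fixed so the many ~MB-sized group arrays
    are always mmap-backed and returned to the OS when freed; otherwise long
    sequences of large tables (the subgroup search) ratchet the heap."""
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(ctypes.c_int(-3), ctypes.c_int(131072))  # M_MMAP_THRESHOLD
    except Exception:
        pass


_pin_mmap_threshold()

# soft caps steering the split; memory stays ~1 GB below these
_LEFT_CAP = 4.0e7
_INNER_CAP = 3.0e7


def fisher_exact_rx2(table: Sequence[Sequence[int]]) -> float:
    """Exact two-sided p-value for an R x 2 table of nonnegative counts.

    ``table`` is an iterable of (a_i, b_i) rows. Probability-ordering
    criterion, fixed margins, exact enumeration (see module docstring).
    Results are cached (the test is deterministic and the subgroup search
    revisits tables); row order does not affect the p-value.
    """
    key = tuple(sorted((int(a), int(b)) for a, b in table))
    hit = _CACHE.get(key)
    if hit is not None:
        return hit
    p = _fisher_exact_rx2_uncached(table)
    if len(_CACHE) < 65536:
        _CACHE[key] = p
    if sum(a + b for a, b in key) > 200:
        _release_memory()
    return p


def _release_memory() -> None:
    """Free the per-call working set promptly after a large enumeration.

    The recursive streaming closure forms a reference cycle, so ~GB-sized
    group dictionaries otherwise wait for the cyclic collector; collect now
    and hand freed pages back to the OS so long sequences of big tables
    (the subgroup search) do not ratchet RSS."""
    import gc

    gc.collect()
    try:  # glibc only; harmless to skip elsewhere
        import ctypes

        ctypes.CDLL("libc.so.6").malloc_trim(0)
    except Exception:
        pass


_CACHE: dict[tuple, float] = {}


def _fisher_exact_rx2_uncached(table: Sequence[Sequence[int]]) -> float:
    rows = [(int(a), int(b)) for a, b in table]
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    for a, b in rows:
        if a < 0 or b < 0:
            raise ValueError("counts must be nonnegative")
    rows = [(a, b) for a, b in rows]
    r = np.array([a + b for a, b in rows], dtype=np.int64)
    if (r == 0).any():
        # empty rows carry no information; drop them
        rows = [(a, b) for a, b in rows if a + b > 0]
        r = np.array([a + b for a, b in rows], dtype=np.int64)
        if len(rows) < 2:
            return 1.0
    c1 = sum(a for a, _ in rows)
    c2 = sum(b for _, b in rows)
    N = int(c1 + c2)
    if c1 == 0 or c2 == 0:
        return 1.0  # single attainable table

    lw = []  # per row: ln C(r_i, a) for a = 0..r_i
    for ri in r:
        a = np.arange(ri + 1)
        lw.append(gammaln(ri + 1) - gammaln(a + 1) - gammaln(ri - a + 1))
    l_obs = float(sum(lw[i][rows[i][0]] for i in range(len(rows))))
    thresh = l_obs + math.log1p(TIE_REL)

    left, inner, outer = _split_rows(r)

    r_left = int(r[left].sum()) if left else 0
    r_inner = int(r[inner].sum()) if inner else 0
    r_outer = int(r[outer].sum()) if outer else 0
    groupL = _materialize_left(left, lw, r, c1, lo=c1 - r_inner - r_outer)
    acc = _stream_right(inner, outer, lw, r, c1, thresh, groupL, inner_lo=c1 - r_left - r_outer)

    log_total = float(gammaln(N + 1) - gammaln(c1 + 1) - gammaln(N - c1 + 1))
    p = acc / math.exp(log_total)
    # guard against float fuzz at the extremes
    return min(1.0, max(p, math.exp(l_obs - log_total)))


def _split_rows(r: np.ndarray) -> tuple[list[int], list[int], list[int]]:
    """Assign rows (indices) to the materialized left half and the enumerated
    right half (an inner vectorized grid plus, when the right half is too big
    for one grid, streamed outer loops).

    The join between the halves is implicit (one binary search per right
    tuple), so the cost is ~max(prod_left, prod_right): grow the left half
    while that max shrinks, under the memory cap.
    """
    order = list(np.argsort(-r))
    rest = order[:]
    left: list[int] = []
    prod_left = 1.0
    prod_rest = float(np.prod((r[order] + 1).astype(float)))
    while len(rest) > 1:
        cand = rest[0]
        new_left = prod_left * (r[cand] + 1)
        new_rest = prod_rest / (r[cand] + 1)
        if new_left > _LEFT_CAP:
            break
        if max(new_left, new_rest) >= max(prod_left, prod_rest):
            break
        left.append(cand)
        prod_left, prod_rest = new_left, new_rest
        rest = rest[1:]
    inner: list[int] = []
    prod_inner = 1.0
    outer: list[int] = []
    for i in rest:
        if prod_inner * (r[i] + 1) <= _INNER_CAP:
            inner.append(i)
            prod_inner *= r[i] + 1
        else:
            outer.append(i)
    return left, inner, outer


def _build_groups(rows_idx, lw, r, c1, lo=0):
    """Log-weight arrays of all row-subset sums, grouped by row sum s.

    Built incrementally one row at a time, so no monolithic (product-sized)
    array or argsort is ever materialized. ``lo`` is the smallest group sum
    any completion of the remaining rows can still bring up to c1; smaller
    sums are unreachable and dropped as soon as that is knowable.
    """
    groups: dict[int, np.ndarray] = {0: np.zeros(1)}
    rest = int(r[rows_idx].sum()) if len(rows_idx) else 0
    for i in rows_idx:
        rest -= int(r[i])
        ri = int(r[i])
        lens: dict[int, int] = {}
        for s, arr in groups.items():
            for a in range(ri + 1):
                s2 = s + a
                if s2 > c1 or s2 + rest < lo:
                    continue
                lens[s2] = lens.get(s2, 0) + arr.size
        new = {s: np.empty(n) for s, n in lens.items()}
        fill = dict.fromkeys(lens, 0)
        for s, arr in groups.items():
            for a in range(ri + 1):
                s2 = s + a
                if s2 > c1 or s2 + rest < lo:
                    continue
                k = fill[s2]
                np.add(arr, lw[i][a], out=new[s2][k: k + arr.size])
                fill[s2] = k + arr.size
        groups = new
    return groups


def _materialize_left(left, lw, r, c1, lo=0):
    """Per achievable left row-sum s: (sorted log-weights, cumulative masses)."""
    out = {}
    for s, arr in _build_groups(left, lw, r, c1, lo).items():
        arr.sort()
        out[s] = (arr, np.cumsum(np.exp(arr)))
    return out


def _stream_right(inner, outer, lw, r, c1, thresh, groupL, inner_lo=0):
    inner_groups = {
        s: (arr, np.exp(arr))
        for s, arr in _build_groups(inner, lw, r, c1, inner_lo).items()
    }
    svals = sorted(inner_groups)

    acc = 0.0

    def visit(s0: int, l0: float) -> None:
        nonlocal acc
        w0 = math.exp(l0)
        for sv in svals:
            g = groupL.get(c1 - s0 - sv)
            if g is None:
                continue
            li, wi = inner_groups[sv]
            x = thresh - l0 - li
            pos = np.searchsorted(g[0], x, side="right")
            nz = pos > 0
            if nz.any():
                acc += w0 * float(np.dot(wi[nz], g[1][pos[nz] - 1]))

    def rec(k: int, s0: int, l0: float) -> None:
        if k == len(outer):
            visit(s0, l0)
            return
        i = outer[k]
        for a in range(min(int(r[i]), c1 - s0) + 1):
            rec(k + 1, s0 + a, l0 + lw[i][a])

    rec(0, 0, 0.0)
    return acc


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Convenience wrapper for the 2 x 2 case (same criterion)."""
    return fisher_exact_rx2([(a, b), (c, d)])


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction.

    Returns (H, df, p) with df = k - 1 and p from the chi-squared upper tail.
    Identical values across all groups give H = 0, p = 1.
    """
    groups = [list(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    df = len(groups) - 1
    flat = {v for g in groups for v in g}
    if len(flat) == 1:
        return 0.0, df, 1.0
    h, p = _scipy_kruskal(*groups)
    return float(h), df, float(p)
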