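"""Approximate MINE grid search backing the maximal information coefficient.

The estimator follows the standard approximate search: one axis is
equipartitioned into ``q`` bins, the other axis is partitioned by a dynamic
program over "clumps" (maximal runs of points that share a row and may not be
split), maximising the grid mutual information for every admissible column
count.  Grid resolutions are limited by ``x * y <= B(n)``.  All heavy loops
are JIT-compiled with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["approx_mic"]


@njit(cache=True)
def _equipartition(v_sorted: np.ndarray, q: int) -> np.ndarray:
    """Assign each (sorted) value a bin 0..q-1 of roughly equal counts.

    Tied values always share a bin.  Returns the bin id per sorted position.
    """
    n = v_sorted.shape[0]
    bins = np.empty(n, dtype=np.int64)
    i = 0
    row = 0
    rowsize = 0
    desired = n / q
    while i < n:
        j = i + 1
        while j < n and v_sorted[j] == v_sorted[i]:
            j += 1
        block = j - i
        if rowsize != 0 and abs(rowsize + block - desired) >= abs(rowsize - desired) and row < q - 1:
            row += 1
            rowsize = 0
            remaining_rows = q - row
            desired = (n - i) / remaining_rows
        for t in range(i, j):
            bins[t] = row
        rowsize += block
        i = j
    return bins


@njit(cache=True)
def _clump_sizes(x_sorted: np.ndarray, rows_xorder: np.ndarray) -> np.ndarray:
    """Clump boundaries in x order.

    Points with identical x are fused; a fused group whose members span more
    than one row bin is its own clump, otherwise consecutive groups sharing a
    row merge.  Returns the size of each clump.
    """
    n = x_sorted.shape[0]
    sizes = np.empty(n, dtype=np.int64)
    n_clumps = 0
    i = 0
    prev_row = -2  # -2: nothing yet; -1 marks a mixed-row fused group
    while i < n:
        j = i + 1
        while j < n and x_sorted[j] == x_sorted[i]:
            j += 1
        row = rows_xorder[i]
        for t in range(i + 1, j):
            if rows_xorder[t] != row:
                row = -1
                break
        if n_clumps > 0 and row != -1 and row == prev_row:
            sizes[n_clumps - 1] += j - i
        else:
            sizes[n_clumps] = j - i
            n_clumps += 1
        prev_row = row
        i = j
    return sizes[:n_clumps]


@njit(cache=True)
def _superclumps(sizes: np.ndarray, khat: int) -> np.ndarray:
    """Merge consecutive clumps down to at most ``khat`` superclumps."""
    k = sizes.shape[0]
    if k <= khat:
        return sizes
    n = 0
    for i in range(k):
        n += sizes[i]
    out = np.zeros(khat, dtype=np.int64)
    used = 0
    cur = 0
    placed = 0
    desired = n / khat
    for i in range(k):
        if cur != 0 and abs(cur + sizes[i] - desired) >= abs(cur - desired) and used < khat - 1:
            used += 1
            cur = 0
            desired = (n - placed) / (khat - used)
        out[used] += sizes[i]
        cur += sizes[i]
        placed += sizes[i]
    return out[: used + 1]


@njit(cache=True)
def _entropy_from_counts(counts: np.ndarray, total: float) -> float:
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * np.log(p)
    return h


@njit(cache=True)
def _optimize_axis(cum: np.ndarray, npts: np.ndarray, n: int, q: int, p_max: int,
                   best: np.ndarray) -> None:
    """DP over clump prefixes: for each column count l=2..p_max record the
    maximal I(P;Q), writing ``best[l] = max(best[l], I_l)``.

    ``cum[t, r]`` counts points of row r within the first t clumps;
    ``npts[t]`` is the total point count of the first t clumps.
    """
    k = cum.shape[0] - 1
    if k < 2:
        return
    hq = _entropy_from_counts(cum[k], float(n))
    # cost(s, t): (m_st / n) * H(rows | column spanning clumps s..t-1)
    cost = np.empty((k + 1, k + 1), dtype=np.float64)
    for s in range(k + 1):
        for t in range(s + 1, k + 1):
            m = npts[t] - npts[s]
            h = 0.0
            for r in range(q):
                c = cum[t, r] - cum[s, r]
                if c > 0:
                    p = c / m
                    h -= p * np.log(p)
            cost[s, t] = (m / n) * h
    lmax = min(p_max, k)
    # F[t]: minimal total cost splitting first t clumps into exactly l columns
    prev = np.empty(k + 1, dtype=np.float64)
    curr = np.empty(k + 1, dtype=np.float64)
    for t in range(k + 1):
        prev[t] = cost[0, t] if t >= 1 else np.inf
    for l in range(2, lmax + 1):
        for t in range(k + 1):
            if t < l:
                curr[t] = np.inf
                continue
            bestv = np.inf
            for s in range(l - 1, t):
                v = prev[s] + cost[s, t]
                if v < bestv:
                    bestv = v
            curr[t] = bestv
        i_l = hq - curr[k]
        if i_l > best[l]:
            best[l] = i_l
        tmp = prev
        prev = curr
        curr = tmp


@njit(cache=True)
def _orientation_scores(col_vals_sorted: np.ndarray, rows_colorder: np.ndarray,
                        n: int, q: int, p_max: int, c: int, best: np.ndarray) -> None:
    sizes = _clump_sizes(col_vals_sorted, rows_colorder)
    khat = max(p_max + 1, c * p_max)
    sizes = _superclumps(sizes, khat)
    k = sizes.shape[0]
    cum = np.zeros((k + 1, q), dtype=np.int64)
    npts = np.zeros(k + 1, dtype=np.int64)
    pos = 0
    for t in range(k):
        for r in range(q):
            cum[t + 1, r] = cum[t, r]
        for _ in range(sizes[t]):
            cum[t + 1, rows_colorder[pos]] += 1
            pos += 1
        npts[t + 1] = pos
    _optimize_axis(cum, npts, n, q, p_max, best)


@njit(cache=True)
def _mic_kernel(x: np.ndarray, y: np.ndarray, b_max: int, c: int) -> float:
    n = x.shape[0]
    ox = np.argsort(x, kind="mergesort")
    oy = np.argsort(y, kind="mergesort")
    xs = x[ox]
    ys = y[oy]
    mic = 0.0
    for q in range(2, b_max // 2 + 1):
        p_max = b_max // q
        if p_max < 2:
            break
        best = np.full(p_max + 1, -1.0)
        # orientation A: rows from y equipartition, columns on x
        rows_of_point = np.empty(n, dtype=np.int64)
        ybins = _equipartition(ys, q)
        for i in range(n):
            rows_of_point[oy[i]] = ybins[i]
        _orientation_scores(xs, rows_of_point[ox], n, q, p_max, c, best)
        # orientation B: rows from x equipartition, columns on y
        xbins = _equipartition(xs, q)
        for i in range(n):
            rows_of_point[ox[i]] = xbins[i]
        _orientation_scores(ys, rows_of_point[oy], n, q, p_max, c, best)
        for l in range(2, p_max + 1):
            if best[l] > 0.0:
                denom = np.log(min(l, q))
                v = best[l] / denom
                if v > mic:
                    mic = v
    if mic > 1.0:
        mic = 1.0
    return mic


def approx_mic(x: np.ndarray, y: np.ndarray, alpha: float = 0.6, c: int = 5) -> float:
    """Maximal information coefficient via the approximate MINE search.

    Parameters
    ----------
    x, y : 1-D float arrays of equal length (n >= 10).
    alpha : grid-size exponent; admissible grids satisfy ``nx * ny <= n**alpha``.
    c : superclump factor — the column-optimised axis is pre-chopped into at
        most ``c * p_max`` clumps before the dynamic program runs.
    """
    n = x.shape[0]
    b_max = int(n ** alpha)
    if b_max < 4:
        b_max = 4
    return float(_mic_kernel(np.ascontiguousarray(x, dtype=np.float64),
                             np.ascontiguousarray(y, dtype=np.float64),
                             b_max, c))
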