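"""Maximal information coefficient (MIC) for general bivariate dependence.

MIC scans axis-aligned grids with at most B(n) = n^0.6 cells, computes the
mutual information of the induced joint distribution for each grid shape
(kx, ky), normalizes by log(min(kx, ky)), and reports the maximum.  It is 0
for independent variables and 1 for noiseless functional relationships, and
depends on the data only through value order, so it is invariant to strictly
monotone transformations of either variable.

``method="approx"`` follows the standard heuristic: one axis is
equipartitioned and the other optimized by dynamic programming over clumps
(with a c * k cap on candidate boundaries), in both orientations.
``method="exact"`` exhaustively enumerates every admissible grid and is
limited to n <= 12; it serves as an oracle for the heuristic.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from numba import njit

__all__ = ["mic"]


def mic(x, y, alpha: float = 0.6, c: int = 15, method: str = "approx") -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("constant input vector; MIC is 0", stacklevel=2)
        return 0.0
    B = max(n ** alpha, 4.0)
    if method == "exact":
        if n > 12:
            raise ValueError("exact MIC is limited to n <= 12")
        return _mic_exact(x, y, B)
    if method != "approx":
        raise ValueError(f"unknown method {method!r}")
    best = 0.0
    for xs, ys in ((x, y), (y, x)):
        best = max(best, _mic_one_orientation(xs, ys, B, c))
    return best


# ---------------------------------------------------------------------------
# approx mode

def _equipartition(v: np.ndarray, q: int) -> np.ndarray:
    """Assign each point to one of <= q rows, near-equal sizes, ties together."""
    n = v.size
    order = np.argsort(v, kind="mergesort")
    rows = np.empty(n, dtype=np.int64)
    desired = n / q
    row, in_row = 0, 0
    i = 0
    sv = v[order]
    while i < n:
        j = i
        while j < n and sv[j] == sv[i]:
            j += 1
        size = j - i
        if in_row > 0 and row < q - 1 and (in_row + size - desired) > (desired - in_row):
            row += 1
            in_row = 0
        rows[order[i:j]] = row
        in_row += size
        i = j
    return rows


def _clumps(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Boundaries (cumulative point counts) of clumps along the x axis.

    Points with equal x stay together; maximal runs of consecutive points in
    the same y-row merge into one clump.
    """
    order = np.lexsort((rows, x))
    xs, rs = x[order], rows[order]
    n = x.size
    boundaries = [0]
    i = 0
    prev_pure_row = -2  # row of previous clump if pure, -2 if none/mixed
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        group_rows = rs[i:j]
        pure = (group_rows == group_rows[0]).all()
        if pure and group_rows[0] == prev_pure_row:
            boundaries[-1] = j  # merge with previous clump
        else:
            boundaries.append(j)
            prev_pure_row = group_rows[0] if pure else -2
        i = j
    if boundaries[0] == 0 and len(boundaries) > 1 and boundaries[1] == 0:
        boundaries.pop(0)
    if boundaries[0] != 0:
        boundaries = [0] + boundaries
    return order, np.asarray(boundaries[1:], dtype=np.int64)  # exclusive ends


def _superclumps(ends: np.ndarray, n: int, k_hat: int) -> np.ndarray:
    if ends.size <= k_hat:
        return ends
    desired = n / k_hat
    out = []
    target = desired
    for e in ends:
        if e >= target or e == ends[-1]:
            out.append(e)
            target = e + desired
    return np.asarray(out, dtype=np.int64)


@njit(cache=False)
def _dp_best(cum: np.ndarray, kx_max: int) -> np.ndarray:
    """G(t, l) = max over l-column partitions of the first t clumps of
    H(P) - H(P, Q), with the published rescaling recurrence.  Returns
    G(m, l) for l = 1..kx_max."""
    m = cum.shape[0] - 1
    q = cum.shape[1]
    cnt = np.zeros(m + 1)
    for t in range(m + 1):
        s = 0.0
        for r in range(q):
            s += cum[t, r]
        cnt[t] = s

    G = np.full((m + 1, kx_max + 1), -np.inf)
    for t in range(1, m + 1):
        h = 0.0
        for r in range(q):
            p = cum[t, r] / cnt[t]
            if p > 0:
                h -= p * np.log(p)
        G[t, 1] = -h
    for l in range(2, kx_max + 1):
        for t in range(l, m + 1):
            best = -np.inf
            for s in range(l - 1, t):
                hseg = 0.0
                seg = cnt[t] - cnt[s]
                for r in range(q):
                    p = (cum[t, r] - cum[s, r]) / seg
                    if p > 0:
                        hseg -= p * np.log(p)
                val = (cnt[s] / cnt[t]) * G[s, l - 1] - (seg / cnt[t]) * hseg
                if val > best:
                    best = val
            G[t, l] = best
    out = np.empty(kx_max + 1)
    for l in range(kx_max + 1):
        out[l] = G[m, l]
    return out


def _mic_one_orientation(x: np.ndarray, y: np.ndarray, B: float, c: int) -> float:
    n = x.size
    best = 0.0
    q_max = int(np.floor(B / 2.0))
    for q in range(2, q_max + 1):
        kx_max = int(np.floor(B / q))
        if kx_max < 2:
            break
        rows = _equipartition(y, q)
        q_eff = int(rows.max()) + 1
        hq = _entropy(np.bincount(rows, minlength=q_eff) / n)
        order, ends = _clumps(x, rows)
        ends = _superclumps(ends, n, max(c * kx_max, 2 * kx_max))
        m = ends.size
        cum = np.zeros((m + 1, q_eff), dtype=np.float64)
        rs = rows[order]
        prev = 0
        for t, e in enumerate(ends, start=1):
            cum[t] = cum[t - 1] + np.bincount(rs[prev:e], minlength=q_eff)
            prev = e
        kx_cap = min(kx_max, m)
        if kx_cap < 2:
            continue
        G = _dp_best(cum, kx_cap)
        run_best = -np.inf
        for l in range(2, kx_cap + 1):
            run_best = max(run_best, G[l])
            i_val = hq + run_best
            best = max(best, i_val / np.log(min(l, q)))
    return best


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# exact mode (tiny n): enumerate every admissible grid

def _mic_exact(x: np.ndarray, y: np.ndarray, B: float) -> float:
    n = x.size
    xcuts = _candidate_cuts(x)
    ycuts = _candidate_cuts(y)
    best = 0.0
    for kx in range(2, int(np.floor(B / 2.0)) + 1):
        for ky in range(2, int(np.floor(B / kx)) + 1):
            if kx * ky > B:
                continue
            for xc in itertools.combinations(xcuts, kx - 1):
                xb = np.digitize(x, xc)
                for yc in itertools.combinations(ycuts, ky - 1):
                    yb = np.digitize(y, yc)
                    joint = np.zeros((kx, ky))
                    for i in range(n):
                        joint[xb[i], yb[i]] += 1
                    joint /= n
                    i_val = (
                        _entropy(joint.sum(axis=1))
                        + _entropy(joint.sum(axis=0))
                        - _entropy(joint.ravel())
                    )
                    best = max(best, i_val / np.log(min(kx, ky)))
    return best


def _candidate_cuts(v: np.ndarray) -> np.ndarray:
    u = np.unique(v)
    return (u[:-1] + u[1:]) / 2.0
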