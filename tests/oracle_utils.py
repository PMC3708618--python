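"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: alignment scores are
obtained by enumerating (or memoising over) whole alignments, segmentation
by a run-length pass over boolean masks, RMSD by an explicit per-point loop.
"""

from __future__ import annotations

import math
from itertools import groupby


def enumerate_affine_best_score(x, y, score, gap_open, gap_extend):
    """Best global alignment score by exhaustive enumeration of alignment
    paths; a run of k gap symbols in one row costs gap_open + (k-1)*gap_extend.
    Exponential: only for tiny strings."""
    best = -math.inf

    def rec(i, j, prev, acc):
        nonlocal best
        if i == len(x) and j == len(y):
            best = max(best, acc)
            return
        if i < len(x) and j < len(y):
            rec(i + 1, j + 1, "M", acc + score(x[i], y[j]))
        if i < len(x):
            rec(i + 1, j, "X", acc + (gap_extend if prev == "X" else gap_open))
        if j < len(y):
            rec(i, j + 1, "Y", acc + (gap_extend if prev == "Y" else gap_open))

    rec(0, 0, None, 0.0)
    return best


def memo_affine_best_score(x, y, score, gap_open, gap_extend, _memo=None):
    """Best global affine-gap score by top-down recursion over string
    suffixes with memoisation (shared across calls via a caller-supplied
    dict, so sweeping many related pairs is cheap)."""
    memo = _memo if _memo is not None else {}

    def rec(xs, ys, prev):
        key = (xs, ys, prev)
        if key in memo:
            return memo[key]
        if not xs and not ys:
            return 0.0
        best = -math.inf
        if xs and ys:
            best = score(xs[0], ys[0]) + rec(xs[1:], ys[1:], "M")
        if xs:
            g = (gap_extend if prev == "X" else gap_open) + rec(xs[1:], ys, "X")
            best = max(best, g)
        if ys:
            g = (gap_extend if prev == "Y" else gap_open) + rec(xs, ys[1:], "Y")
            best = max(best, g)
        memo[key] = best
        return best

    return rec(x, y, None)


def segment_oracle(candidate_mask, min_len):
    """Run-length segmentation of a boolean candidate mask: maximal True
    runs of length >= min_len are SVR, everything else SCR.  Returns
    [(start, end, kind)] tiling the mask."""
    n = len(candidate_mask)
    is_svr = [False] * n
    pos = 0
    for val, grp in groupby(candidate_mask):
        k = len(list(grp))
        if val and k >= min_len:
            for i in range(pos, pos + k):
                is_svr[i] = True
        pos += k
    out = []
    pos = 0
    for val, grp in groupby(is_svr):
        k = len(list(grp))
        out.append((pos, pos + k, "SVR" if val else "SCR"))
        pos += k
    return out


def rmsd_loop(a, b):
    """Fixed-frame RMSD via an explicit per-point loop."""
    assert len(a) == len(b) and len(a) > 0
    acc = 0.0
    for p, q in zip(a, b):
        acc += sum((float(pi) - float(qi)) ** 2 for pi, qi in zip(p, q))
    return math.sqrt(acc / len(a))
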