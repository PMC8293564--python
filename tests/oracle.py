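"""Independent brute-force oracle: full-matrix banded affine-gap DP.

Recomputes from scratch, with numpy over the whole (query x window) matrix,
what the incremental frontier aligner computes one row at a time.  Kept
deliberately separate from the package implementation.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Tuple

import numpy as np

NEG = -(1 << 30)  # matches the implementation sentinel so unreachable rows compare equal


def banded_affine_dp(
    query: str,
    window: str,
    sub: Callable[[str, str], int],
    gap_open: int,
    gap_extend: int,
    band: int,
) -> List[int]:
    """Per-row best scores of aligning query prefixes to window prefixes.

    The alignment is anchored at (0, 0), global in the query, free in the
    window end; cells outside |i - j| <= band are unreachable.  Returns
    row_best[j] for j = 0..len(query).
    """
    n, m = len(query), len(window)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    M[0, 0] = 0
    for i in range(1, m + 1):
        if i <= band:
            Iy[0, i] = -(gap_open + i * gap_extend)
    for j in range(1, n + 1):
        for i in range(max(0, j - band), min(m, j + band) + 1):
            if i >= 1:
                diag = max(M[j - 1, i - 1], Ix[j - 1, i - 1], Iy[j - 1, i - 1])
                if diag > NEG // 2:
                    M[j, i] = diag + sub(query[j - 1], window[i - 1])
            up = max(M[j - 1, i] - gap_open - gap_extend, Ix[j - 1, i] - gap_extend)
            if abs(i - (j - 1)) <= band and up > NEG // 2:
                Ix[j, i] = up
            if i >= 1:
                left = max(M[j, i - 1] - gap_open - gap_extend, Iy[j, i - 1] - gap_extend)
                if left > NEG // 2:
                    Iy[j, i] = left
    best = np.maximum(np.maximum(M, Ix), Iy)
    return [int(best[j].max()) for j in range(n + 1)]


def replay_verdicts(
    row_best: List[int], drop_off: int
) -> Tuple[int, Optional[int], List[str]]:
    """Apply the improve/within/clip rule to a row-score series.

    Returns (best score, best query position or None, verdict per row >= 1).
    """
    best = 0
    best_j: Optional[int] = None
    verdicts = []
    for j in range(1, len(row_best)):
        cur = row_best[j]
        if cur > best:
            best, best_j = cur, j
            verdicts.append("improved")
        elif best - cur <= drop_off:
            verdicts.append("within_dropoff")
        else:
            verdicts.append("clip")
    return best, best_j, verdicts


def count_source_sink_paths(segments, links, cap: int = 100000) -> int:
    """Independent path counter for small DAG-ified graphs (link-once rule)."""
    preds = {s: [] for s in segments}
    succs = {s: [] for s in segments}
    for f, t in links:
        succs[f].append(t)
        preds[t].append(f)
    sources = [s for s in sorted(segments) if not preds[s]] or [min(segments)]
    total = 0
    for src in sources:
        stack = [(src, frozenset())]
        while stack:
            node, used = stack.pop()
            nxt = [t for t in succs[node] if (node, t) not in used]
            if not nxt:
                total += 1
                if total > cap:
                    return total
                continue
            for t in nxt:
                stack.append((t, used | {(node, t)}))
    return total
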