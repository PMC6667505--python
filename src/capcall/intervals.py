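"""Half-open interval algebra on integer coordinates.

All functions operate on (n, 2) integer arrays of [start, end) rows on a single
sequence. Inputs need not be sorted; outputs are sorted, non-overlapping and
non-empty. These primitives back the annotation hierarchy flattening, union-TSS
merging and truth-set masks.
"""

from __future__ import annotations

import numpy as np


def _as_array(ivs) -> np.ndarray:
    a = np.asarray(ivs, dtype=np.int64)
    if a.size == 0:
        return a.reshape(0, 2)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("intervals must be an (n, 2) array of [start, end)")
    return a


def merge(ivs, gap: int = 0) -> np.ndarray:
    """Union of intervals; rows closer than or equal to `gap` are fused.

    gap=0 fuses overlapping *and* bookended intervals, which is what a flattened
    per-base map needs. Callers that must keep bookended rows distinct pass
    gap=-1 (fuse only true overlaps).
    """
    a = _as_array(ivs)
    a = a[a[:, 0] < a[:, 1]]
    if len(a) == 0:
        return a
    a = a[np.lexsort((a[:, 1], a[:, 0]))]
    out = []
    cs, ce = a[0]
    for s, e in a[1:]:
        if s - ce <= gap:
            ce = max(ce, e)
        else:
            out.append((cs, ce))
            cs, ce = s, e
    out.append((cs, ce))
    return np.array(out, dtype=np.int64)


def subtract(a, b) -> np.ndarray:
    """Bases of `a` not covered by `b` (a \\ b)."""
    a = merge(a)
    b = merge(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def intersect(a, b) -> np.ndarray:
    """Bases covered by both `a` and `b`."""
    a = merge(a)
    b = merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def total_length(ivs) -> int:
    m = merge(ivs)
    return int((m[:, 1] - m[:, 0]).sum()) if len(m) else 0


def point_in(ivs, pos: int) -> bool:
    a = merge(ivs)
    if len(a) == 0:
        return False
    i = int(np.searchsorted(a[:, 0], pos, side="right")) - 1
    return i >= 0 and a[i, 0] <= pos < a[i, 1]


def gap_to_point(ivs, pos: int) -> int | None:
    """Distance from `pos` to the nearest interval; 0 when inside; None if empty."""
    a = merge(ivs)
    if len(a) == 0:
        return None
    d = np.where(
        (a[:, 0] <= pos) & (pos < a[:, 1]),
        0,
        np.minimum(np.abs(a[:, 0] - pos), np.abs((a[:, 1] - 1) - pos)),
    )
    return int(d.min())
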