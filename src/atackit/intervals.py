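"""Interval arithmetic on 0-based half-open genomic intervals.

All functions operate on a single contig's intervals represented as an
``(n, 2)`` int64 array of ``(start, end)`` rows. Multi-contig collections
are plain ``dict[str, ndarray]`` handled by callers.
"""

from __future__ import annotations

import numpy as np

EMPTY = np.empty((0, 2), dtype=np.int64)


def as_array(intervals) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to a canonical (n, 2) array."""
    arr = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals,
                     dtype=np.int64)
    if arr.size == 0:
        return EMPTY.copy()
    return arr.reshape(-1, 2)


def merge(intervals, gap: int = 0) -> np.ndarray:
    """Merge overlapping (or within ``gap`` bp) intervals into disjoint sorted ones."""
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def total_length(intervals) -> int:
    """Total covered base pairs of a *merged* interval set."""
    arr = as_array(intervals)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


def intersect(a, b) -> np.ndarray:
    """Pairwise intersection of two merged, sorted interval sets."""
    a, b = as_array(a), as_array(b)
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
    return as_array(out)


def subtract(a, b) -> np.ndarray:
    """Bases of merged set ``a`` not covered by merged set ``b``."""
    a, b = as_array(a), as_array(b)
    if len(a) == 0 or len(b) == 0:
        return a.copy()
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return as_array(out)


def complement(intervals, length: int) -> np.ndarray:
    """Complement of a merged interval set over ``[0, length)``."""
    return subtract([(0, length)], intervals)


def overlaps_any(queries, intervals) -> np.ndarray:
    """Boolean per query: does it overlap (>= 1 bp) any interval in the merged set?"""
    q = as_array(queries)
    iv = as_array(intervals)
    if len(q) == 0:
        return np.zeros(0, dtype=bool)
    if len(iv) == 0:
        return np.zeros(len(q), dtype=bool)
    # last interval starting before the query end is the only merge-sorted candidate
    idx = np.searchsorted(iv[:, 0], q[:, 1], side="left")
    hit = idx > 0
    hit[hit] = iv[idx[hit] - 1, 1] > q[hit, 0]
    return hit
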