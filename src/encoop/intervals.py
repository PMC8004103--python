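"""Small exact-boundary interval primitives.

All coordinates are 0-based half-open. ``gap_distance`` is 0 for touching or
overlapping intervals, otherwise the number of bases strictly between them —
the convention every distance threshold in this package relies on.
"""

from __future__ import annotations

import numpy as np


def gap_distance(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap between two intervals; 0 when they overlap or touch."""
    if start_a < end_b and start_b < end_a:
        return 0
    if end_a <= start_b:
        return start_b - end_a
    return start_a - end_b


def min_gap_to_set(start: int, end: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Minimum gap from [start, end) to any interval in a (possibly unsorted) set."""
    if len(starts) == 0:
        return np.iinfo(np.int64).max
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    left = starts - end          # b fully right of a
    right = start - ends         # b fully left of a
    gaps = np.maximum(np.maximum(left, right), 0)
    return int(gaps.min())


def merge_with_gap(starts, ends, max_gap: int = 0):
    """Single-linkage merge of intervals whose gap is <= max_gap.

    Returns (merged_starts, merged_ends, group_index) where group_index maps
    each input interval (in input order) to its merged interval.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    n = len(starts)
    if n == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    order = np.lexsort((ends, starts))
    group = np.empty(n, dtype=np.int64)
    m_starts, m_ends = [], []
    cur_s = cur_e = None
    g = -1
    for idx in order:
        s, e = int(starts[idx]), int(ends[idx])
        if cur_e is None or s - cur_e > max_gap:
            g += 1
            m_starts.append(s)
            m_ends.append(e)
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
            m_ends[-1] = cur_e
        group[idx] = g
    return np.asarray(m_starts), np.asarray(m_ends), group


def containing_interval(pos: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Index of the interval containing position ``pos`` (half-open), or -1."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    hits = np.flatnonzero((starts <= pos) & (pos < ends))
    return int(hits[0]) if len(hits) else -1
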