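"""Half-open integer interval arithmetic.

Every interval is a ``(start, end)`` pair with ``0 <= start < end``,
interpreted as the 0-based half-open genomic interval ``[start, end)``.
Functions returning interval lists always return them merged (no
overlaps, no adjacent touching intervals) and sorted by start.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or touching intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets (inputs need not be merged)."""
    a, b = merge(a), merge(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intervals of ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals: Iterable[Interval], start: int, end: int) -> List[Interval]:
    return intersect(intervals, [(start, end)])


def contains_point(merged: List[Interval], pos: int) -> bool:
    """Membership test against a merged, sorted interval list."""
    i = bisect_right(merged, (pos, float("inf"))) - 1
    return i >= 0 and merged[i][0] <= pos < merged[i][1]
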