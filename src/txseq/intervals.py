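"""Half-open interval algebra on plain ``(start, end)`` tuples.

All functions take and return sorted, disjoint interval lists. Intervals are
0-based half-open throughout the package.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list (touching runs merge)."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two sorted disjoint interval lists."""
    out: list[Interval] = []
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


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def overlap_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    return total_length(intersect(merge(a), merge(b)))


def contains(cover: Sequence[Interval], start: int, end: int) -> bool:
    """True if [start, end) is entirely inside the (sorted, disjoint) cover."""
    if end <= start:
        return True
    i = bisect_right(cover, (start, float("inf"))) - 1
    if i < 0:
        return False
    s, e = cover[i]
    return s <= start and end <= e


def overlaps_any(cover: Sequence[Interval], start: int, end: int) -> bool:
    """True if [start, end) overlaps any interval of the sorted cover."""
    if end <= start:
        return False
    i = bisect_right(cover, (start, float("inf"))) - 1
    if i >= 0 and cover[i][1] > start:
        return True
    return i + 1 < len(cover) and cover[i + 1][0] < end
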