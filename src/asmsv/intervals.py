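"""Sorted half-open interval sets with union/subtract/intersect.

All coordinates are 0-based half-open ``[start, end)``. The class is a thin
wrapper over a sorted, merged list of ``(start, end)`` tuples; operations are
linear sweeps, which is plenty for per-chromosome exclusion masks.
"""

from __future__ import annotations

import bisect
from typing import Iterable, Iterator, List, Tuple

Interval = Tuple[int, int]


def merge_intervals(ivs: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or touching half-open intervals."""
    out: List[Interval] = []
    for lo, hi in sorted((lo, hi) for lo, hi in ivs if hi > lo):
        if out and lo <= out[-1][1]:
            if hi > out[-1][1]:
                out[-1] = (out[-1][0], hi)
        else:
            out.append((lo, hi))
    return out


class IntervalSet:
    """An immutable set of disjoint, sorted half-open intervals."""

    __slots__ = ("_ivs", "_starts")

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        self._ivs = merge_intervals(intervals)
        self._starts = [lo for lo, _ in self._ivs]

    @property
    def intervals(self) -> List[Interval]:
        return list(self._ivs)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._ivs)

    def __len__(self) -> int:
        return len(self._ivs)

    def __bool__(self) -> bool:
        return bool(self._ivs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self._ivs == other._ivs

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({self._ivs!r})"

    def total_length(self) -> int:
        return sum(hi - lo for lo, hi in self._ivs)

    def contains_point(self, pos: int) -> bool:
        i = bisect.bisect_right(self._starts, pos) - 1
        return i >= 0 and pos < self._ivs[i][1]

    def contains_interval(self, lo: int, hi: int) -> bool:
        """True iff [lo, hi) lies entirely within one stored interval."""
        if hi <= lo:
            return self.contains_point(lo)
        i = bisect.bisect_right(self._starts, lo) - 1
        return i >= 0 and self._ivs[i][0] <= lo and hi <= self._ivs[i][1]

    def overlap(self, lo: int, hi: int) -> int:
        """Number of bases of [lo, hi) covered by the set."""
        total = 0
        i = max(bisect.bisect_right(self._starts, lo) - 1, 0)
        while i < len(self._ivs) and self._ivs[i][0] < hi:
            a, b = self._ivs[i]
            total += max(0, min(b, hi) - max(a, lo))
            i += 1
        return total

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(self._ivs + other._ivs)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: List[Interval] = []
        i = j = 0
        a, b = self._ivs, other._ivs
        while i < len(a) and j < len(b):
            lo = max(a[i][0], b[j][0])
            hi = min(a[i][1], b[j][1])
            if hi > lo:
                out.append((lo, hi))
            if a[i][1] < b[j][1]:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: List[Interval] = []
        j = 0
        b = other._ivs
        for lo, hi in self._ivs:
            cur = lo
            while j < len(b) and b[j][1] <= cur:
                j += 1
            k = j
            while k < len(b) and b[k][0] < hi:
                if b[k][0] > cur:
                    out.append((cur, b[k][0]))
                cur = max(cur, b[k][1])
                k += 1
            if cur < hi:
                out.append((cur, hi))
        return IntervalSet(out)
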