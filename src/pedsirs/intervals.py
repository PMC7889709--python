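"""Half-open time-interval algebra on pandas Timestamps.

All functions operate on lists of ``(start, end)`` tuples with ``start < end``,
interpreted as the half-open interval ``[start, end)``. Outputs are always
sorted and pairwise disjoint.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import pandas as pd

Interval = Tuple[pd.Timestamp, pd.Timestamp]


def normalize(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort, drop empties, and merge touching/overlapping intervals."""
    ivs = sorted((pd.Timestamp(s), pd.Timestamp(e)) for s, e in intervals if s < e)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def union(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    return normalize(list(a) + list(b))


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    i = j = 0
    a = normalize(a)
    b = normalize(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b."""
    a = normalize(a)
    b = normalize(b)
    out: list[Interval] = []
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
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals: Sequence[Interval], lo: pd.Timestamp, hi: pd.Timestamp) -> list[Interval]:
    return intersect(intervals, [(lo, hi)]) if lo < hi else []


def total_duration(intervals: Sequence[Interval]) -> pd.Timedelta:
    tot = pd.Timedelta(0)
    for s, e in intervals:
        tot += e - s
    return tot


def covers(intervals: Sequence[Interval], t: pd.Timestamp) -> bool:
    """Point membership t ∈ ∪ intervals (half-open semantics)."""
    for s, e in intervals:
        if s <= t < e:
            return True
    return False
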