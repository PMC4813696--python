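"""Half-open interval arithmetic on (start, end) pairs.

All intervals are 0-based, half-open and live on a single reference
sequence; callers are responsible for grouping by chromosome first.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals as a sorted, non-overlapping, non-adjacent list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets (each merged internally first)."""
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


def intersect_length(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intersect(a, b))


def contains(container: Iterable[Interval], s: int, e: int) -> bool:
    """True if [s, e) lies entirely inside the union of ``container``."""
    return any(cs <= s and e <= ce for cs, ce in merge(container))
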