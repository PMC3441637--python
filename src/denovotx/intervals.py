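"""Half-open genomic interval arithmetic used by the expression module."""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]

__all__ = ["merge", "subtract", "total_length", "overlaps"]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of half-open intervals, sorted and non-overlapping."""
    out: List[Interval] = []
    for start, end in sorted(intervals):
        if end <= start:
            continue
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Portions of ``a`` not covered by ``b`` (both half-open)."""
    b_merged = merge(b)
    out: List[Interval] = []
    for start, end in merge(a):
        cursor = start
        for bs, be in b_merged:
            if be <= cursor or bs >= end:
                continue
            if bs > cursor:
                out.append((cursor, bs))
            cursor = max(cursor, be)
            if cursor >= end:
                break
        if cursor < end:
            out.append((cursor, end))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(end - start for start, end in merge(intervals))


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]
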