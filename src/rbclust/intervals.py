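"""Half-open interval arithmetic on (start, end) tuples.

These helpers define the package's coordinate semantics (0-based,
half-open, sorted, non-overlapping after ``merge_intervals``) and are
deliberately explicit rather than delegated, since footprint-inclusive
spans and gap conventions are load-bearing throughout the analysis.
"""

from __future__ import annotations

Interval = tuple[int, int]


def validate_intervals(intervals: list[Interval]) -> None:
    for start, end in intervals:
        if start >= end:
            raise ValueError(f"empty or inverted interval ({start}, {end})")


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or book-ended intervals."""
    if not intervals:
        return []
    validate_intervals(intervals)
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Per-base set difference ``a \\ b`` (both merged first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < end:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < end:
            out.append((cur, end))
    return out


def intersect_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Per-base intersection of two interval lists."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(end - start for start, end in merge_intervals(intervals))


def gaps_between(intervals: list[Interval]) -> list[Interval]:
    """Gaps between consecutive merged intervals (introns of an exon chain)."""
    merged = merge_intervals(intervals)
    return [
        (merged[i][1], merged[i + 1][0])
        for i in range(len(merged) - 1)
        if merged[i][1] < merged[i + 1][0]
    ]


def contains_point(intervals: list[Interval], pos: int) -> bool:
    return any(start <= pos < end for start, end in intervals)


def contained_in(inner: list[Interval], outer: list[Interval]) -> bool:
    """True when every base of ``inner`` lies inside ``outer``."""
    return total_length(subtract_intervals(inner, outer)) == 0


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
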